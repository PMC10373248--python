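# carpmove

Movement and behavioral-state analysis of acoustic-tagged common carp
(*Cyprinus carpio*) responding to non-physical deterrents — CO₂ injection
and forced water circulation — inside a navigation lock chamber. The
package is aimed at movement ecologists and invasive-species managers who
want a tested, reusable version of this analysis pipeline, exercised
end-to-end on synthetic trials with known ground truth.

## What it computes

Irregular acoustic-telemetry fixes (transmitter pulse gaps of 1.3–5.9 s)
are first regularized onto a 6-s grid with a continuous-time correlated
random walk (CTCRW): per axis, an integrated Ornstein–Uhlenbeck velocity
process

dv(t) = −β v(t) dt + σ dW(t),  x(t) = x(0) + ∫ v(s) ds,  yᵢ = x(tᵢ) + εᵢ,

fitted by maximum likelihood through a Kalman filter over the irregular fix
times; smoothed positions on the grid yield step lengths and turning
angles.

A two-state hidden Markov model then classifies each 6-s step as
**exploratory** (long steps, near-uniform turning angles) or **encamped**
(short, directionally persistent steps). Step lengths are zero-inflated
gamma with a covariate-linked mean, log m<sub>k</sub> = θ₀ₖ + θ·(trial,
pump, CO₂, temperature); turning angles are von Mises(μₖ, κₖ); and the
switching probabilities are multinomial-logit in the same covariates,
logit ψ₁→₂ = β₀ + β·(trial, pump, CO₂, temperature), so the transition
matrix varies step by step with the CO₂ ramp. Viterbi decoding, forward–
backward state probabilities, and one-step-ahead pseudo-residuals provide
state paths, time budgets, and goodness-of-fit diagnostics.

Alongside the HMM, a Kaplan–Meier time-to-exit analysis treats "survival"
as still being inside the lock, right-censoring fish that have not crossed
the open downstream gate line by the trial horizon (90 min).

The `simulate` module generates ground-truth-known trials that emulate the
study design: a 51.82 m × 11.12 m lock arena with an absorbing gate line,
a 20-trial treatment roster, CO₂ ramping to 100–150 mg/L within 5–10 min,
step-turn kinematics with wall reflection, irregular fix thinning, and
positioning noise calibrated to a 0.878 m median error.

## Worked example

```python
import numpy as np
from carpmove import (
    LockArena, make_treatment_profile, study_default_params, simulate_trial,
    fit_ctcrw, predict_regular, steps_and_angles, fit_hmm, HmmDesign,
    FitOptions, decode, detect_exit,
)

arena = LockArena()                       # 51.82 m x 11.12 m, gate at x = 0
profile = make_treatment_profile("pump_co2", target_co2=125.0)
params = study_default_params()           # study-calibrated ground truth
trial = simulate_trial(arena, profile, params, n_fish=3, seed=42, trial_id=1)

cov = profile.covariate_table(trial_id=1)
series, tracks = [], []
for fixes, truth in trial:
    ctcrw = fit_ctcrw(fixes, seed=0)
    track = predict_regular(fixes, ctcrw)
    tracks.append(track)
    series.append(steps_and_angles(track, cov))

fit = fit_hmm(series, HmmDesign(transition_terms=("co2",), step_terms=("co2",)),
              FitOptions(n_restarts=2, seed=0))
print(f"log-likelihood {fit.loglik:.1f} on {fit.n_obs} steps")
for k, name in ((0, "exploratory"), (1, "encamped")):
    print(f"{name}: mean step {np.exp(fit.params_hat.step.mean[k].intercept):.3f} m"
          f" (SD {fit.params_hat.step.sd(k + 1):.3f})")
for d in decode(fit.params_hat, series):
    rec = detect_exit([t for t in tracks if t.fish_id == d.fish_id][0], arena)
    status = f"exited at {rec.time_min:.1f} min" if rec.event else "censored at 90 min"
    print(f"fish {d.fish_id}: {100 * d.budget:.0f}% exploratory, {status}")
```

prints

```
log-likelihood -746.7 on 2700 steps
exploratory: mean step 0.598 m (SD 0.153)
encamped: mean step 0.130 m (SD 0.066)
fish T1F1: 10% exploratory, censored at 90 min
fish T1F2: 15% exploratory, censored at 90 min
fish T1F3: 13% exploratory, censored at 90 min
```

Under a CO₂ treatment these simulated carp sit mostly in the encamped
state and fail to leave the lock within the 90-min horizon; the fitted
state means are separated but attenuated relative to the latent kinematics
because CTCRW smoothing through ~0.75 m positioning noise shrinks 6-s
displacements (see `docs/methods.md`).

The `carpmove` console script exposes the same pipeline stage by stage
(`simulate`, `regularize`, `fit`, `decode`, `survival`, `all`), driven by a
YAML config; see `carpmove --help`.

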