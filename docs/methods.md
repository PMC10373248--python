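# Methods

## Track regularization: the CTCRW model

Positions from the acoustic array arrive at irregular times (pulse gaps
uniform over 1.301–5.862 s in the simulator, mirroring the transmitters'
programmed range). The regularization model is a continuous-time
correlated random walk: per axis, velocity is an Ornstein–Uhlenbeck
process mean-reverting to zero at rate `beta_vel` (1/s) and driven by
white noise of scale `sigma_vel`; position is the integral of velocity;
observations add Gaussian error with SD `tau_obs` (m). The two axes share
parameters — a parsimony choice appropriate to a lock chamber with no
strong anisotropy in positioning error.

The discrete transition over a gap Δ has exact Gaussian moments, so the
likelihood over irregular times is exact. Numerical points worth noting:

* The position-increment variance involves
  g(u) = u − 2(1 − e^{−u}) + (1 − e^{−2u})/2 with u = βΔ, which suffers
  catastrophic cancellation as u → 0; for u < 10⁻³ the series
  u³/3 − u⁴/4 + 7u⁵/60 is used instead.
* Kalman updates use the Joseph form so the state covariance stays
  positive semidefinite when `tau_obs` is at its lower bound (10⁻⁶ m) —
  which is exactly where noise-free tracks drive it.
* Optimization is L-BFGS-B on log-parameters with 3 seeded restarts
  (box bounds: β ∈ [10⁻⁵, 10³] s⁻¹, σ ∈ [10⁻⁶, 10³], τ ∈ [10⁻⁶, 10²] m).
  Failure of every restart raises an error carrying the best parameters
  found.

Grid prediction uses the fixed-interval (RTS) smoother over the union of
fix times and grid times, anchored at the first fix and never
extrapolating past the last (no positions are invented beyond data
support). A single smoothed track feeds the HMM; the positional
uncertainty of the smoother is reported (`pred_se` = √(var_x + var_y)) but
not propagated into the HMM by multiple imputation — a deliberate
simplification.

**Step attenuation.** Smoothing through positioning noise is a low-pass
filter: 6-s displacements of the smoothed track are systematically shorter
than the latent kinematics, and the encamped state (true steps ~0.03 m
against ~0.75 m noise) is affected most. Fitted state means from
regularized tracks are therefore attenuated relative to the generator's
emission parameters; parameter-recovery claims are made at emission level
(see below), where the estimator is consistent.

## The two-state movement HMM

States: 1 = exploratory (long steps, diffuse turning), 2 = encamped
(short, persistent steps). Per 6-s step the observation is (step length,
turning angle).

* **Step length | state k**: zero-inflated gamma. A logit-scale zero-mass
  parameter gives the probability of an exactly-zero step (a stationary
  fix); otherwise the step is gamma with mean
  m = exp(θ₀ₖ + θ_trial + θ_pump·1[pump off] + θ_CO₂·CO₂ + θ_T·T) and
  SD s = exp(log-SD parameter), moment-matched as shape = m²/s², scale =
  s²/m. SD and zero mass are covariate-free, one working parameter per
  state.
* **Turning angle | state k**: von Mises(μₖ, κₖ), no covariates. The first
  step of a track and steps adjacent to a zero-length step have undefined
  bearing; their angle is missing and contributes a likelihood factor of 1.
  Left turns are positive (counter-clockwise).
* **Switching**: logit ψ₁→₂ and logit ψ₂→₁ are linear in the same
  covariates (two-state multinomial logit). The matrix Γₜ built from the
  covariates of step t governs the transition from step t to step t+1 —
  the same convention the simulator uses. Reference categories: trial 1
  and pump **on** (the pump-off indicator carries the coefficient).
* **Initial distribution**: stationary distribution of Γ at each fish's
  first-step covariates; free estimation is available behind
  `HmmDesign(estimate_delta=True)`.

Links were chosen so every working parameter is unconstrained: logit for
probabilities, log for the gamma mean and SD. Supporting this convention,
the log-SD working value −0.0745 of the calibrated defaults exponentiates
to the 0.928 m exploratory step SD. The analogous encamped entry
(−1.6654 → 0.189 m) does not match the 0.019 m SD quoted alongside it in
the source estimates; the package keeps the log-link convention uniformly
and records the discrepancy here rather than special-casing one entry.

**Fitting.** The forward algorithm (scaled recursions, numba-compiled with
a pure-NumPy fallback) gives the likelihood; L-BFGS-B maximizes it over
all working parameters with seeded random restarts (default 5; the
pipeline and recovery studies use 2 with a moment-based start, which the
restart perturbations make effectively redundant on well-separated data).
Continuous covariates are centered and scaled internally for conditioning;
estimates and their covariance are mapped back to natural scale (per mg/L,
per °C). Convergence tolerance is 10⁻⁸ on the relative log-likelihood
change. Label switching is resolved after fitting: state 1 is the state
with the larger fitted mean step over the data. Standard errors come from
the pseudo-inverse of the numerically differentiated observed information;
weakly identified parameters (angle mean with κ ≈ 0, zero mass with no
zero steps observed) surface as large or degenerate SEs rather than being
constrained away.

**Decoding and diagnostics.** Viterbi (ties prefer exploratory) and
forward–backward posteriors are both exact dynamic programs, verified in
the tests against exhaustive enumeration of all 2^T paths for T ≤ 10.
Per-fish time budgets are the fraction of Viterbi steps in the exploratory
state (posterior thresholding is available via the returned posterior
probabilities); the pooled budget uses pooled step counts. Goodness of fit
uses one-step-ahead pseudo-residuals z = Φ⁻¹(F(obs | past)) with F the
state-conditional CDFs mixed by forward-predictive weights; the angle CDF
is measured from −π. Under the generating model, step residuals are
standard normal to within sampling error (checked at 5,000 steps).

## Time-to-exit analysis

The event is crossing the open downstream gate line (x < gate_x,
downstream = decreasing x); exit time interpolates linearly between the
bracketing grid positions, removing 6-s grid quantization. Fish still
inside at the horizon (default 90 min, configurable per trial) are
right-censored. One extension of the censoring rule: a fix series that
ends well before the horizon (grace 60 s) without crossing means the fish
left receiver coverage through the gate, so by default the track end is
treated as the exit time (`end_of_track_is_exit=False` restores strict
censoring).

The product-limit curve and KM median come from lifelines; the Greenwood
SE is computed from the event table, S(t)·√Σ d/(n(n−d)). Ties between
events and censorings follow the standard events-first convention. Two
medians are reported: the sample median with censored times set to the
horizon (the headline convention), and the KM median as a secondary
output. The proportion remaining carries a binomial SE,
100·√(p̂(1−p̂)/n).

## The synthetic-trial generator

The generator reproduces the study *design*, with exact ground truth
retained for every fish:

* arena 51.82 m × 11.12 m with the full downstream wall as an absorbing
  gate; fish start uniformly in the upstream two-thirds (starting
  positions were not part of the recorded design, so a neutral default was
  chosen) with uniform initial heading;
* a 20-trial roster (12 CO₂ + circulation, 6 circulation-only, 2 null;
  3 fish per trial except three trials with 2 — 34/17/6 fish per
  treatment), CO₂ ramping linearly to a 100–150 mg/L target within 5–10
  min and held, pumps on from gate opening, constant within-trial
  temperature (drawn once per trial around 22 °C for late-summer river
  water);
* step-turn kinematics: heading persists, new heading = old + turning
  angle, displacement along the new heading; specular reflection at walls
  (the fold preserves path length, so exit times within a step are exact);
* emission and switching parameters default to the calibrated field-study
  estimates (`study_default_params()`);
* thinning to irregular fix times (gaps uniform over the pulse range) by
  linear interpolation of the 6-s path, plus isotropic Gaussian noise with
  SD 0.878/√(2 ln 2) ≈ 0.746 m, the value that makes the median 2-D
  position-error norm equal the 0.878 m benchmark.

What it does **not** emulate — and hence what passing tests do not show
about real data: no taxis toward the gate or flow field (movement is
diffusive within a state, so synthetic exit times are much longer than
field-observed ones and most simulated fish are censored); no depth
dimension; no CO₂ chemistry or hydraulics; no spatial variation of
positioning error with hydrophone geometry; no tag loss or missed
detections beyond the pulse-gap thinning.

## Problem sizes and seeds

Recovery and calibration studies use sizes chosen to make estimates
stable while keeping a full run to minutes on one CPU: 30 tracks × 900
steps (one 90-min trial cohort) for HMM recovery, 20 seeded replicates
for the CO₂ sign-recovery rate, 2,000 fixes for CTCRW recovery, 5,000
steps for residual calibration, and the full 20-trial roster for the
end-to-end study run. All randomness flows from explicit integer seeds;
identical seeds give byte-identical pipeline reports (reports contain no
timestamps).

## Known limitations

* Single imputation of the smoothed track understates HMM parameter
  uncertainty and attenuates step lengths (see above).
* SD and zero mass are covariate-free by design; real heteroscedasticity
  in step lengths would be absorbed into state assignment.
* The two-state restriction is inherited from the study design (≤ 90-min
  trials); longer records would support richer state spaces.
* Trial-factor fits (20 levels, ~100 parameters) are supported but slow;
  the pipeline default uses pump/CO₂/temperature only.
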