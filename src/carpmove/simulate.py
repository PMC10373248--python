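"""Ground-truth-known synthetic trials of carp in a navigation lock.

Emulates the study design this package analyzes: tagged carp acclimated in
a closed lock chamber (51.82 m x 11.12 m), the downstream gate opened, and
one of three treatments applied -- CO2 injection with forced water
circulation, forced water circulation only, or a null treatment. Fish move
by two-state switching kinematics (exploratory vs encamped) with the same
emission and covariate-linked transition structure the HMM estimates, so
simulated trials carry exact ground truth for recovery tests.

Movement mechanics (the kinematic conventions, not fitted quantities):
step-turn propagation with a persistent heading (new heading = old heading
+ turning angle; displacement = step length along the new heading), specular
reflection at the chamber walls, and an absorbing gate line at ``gate_x``
(downstream = decreasing x). True positions on the 6-s grid are thinned to
irregular fix times with gaps uniform over the transmitter pulse-rate range
(1.301-5.862 s) and perturbed by isotropic Gaussian positioning noise whose
default SD makes the median 2-D position error 0.878 m.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .hmm import (
    AngleParams,
    HmmParams,
    LinearCoefficients,
    StepCoefficients,
    TransitionCoefficients,
)
from .regularize import FixSeries, StepAngleSeries, wrap_angle

__all__ = [
    "LockArena",
    "TreatmentProfile",
    "SimTruth",
    "SimulatedTrial",
    "make_treatment_profile",
    "simulate_trial",
    "simulate_step_series",
    "write_fixtures",
    "read_fix_table",
    "read_covariate_table",
    "study_roster",
    "study_default_params",
]

DT_S = 6.0
PULSE_GAP_RANGE_S = (1.301, 5.862)
# isotropic Gaussian noise whose 2-D error norm (Rayleigh) has median 0.878 m
POSITION_NOISE_SD_M = 0.878 / np.sqrt(2.0 * np.log(2.0))
TREATMENTS = ("null", "pump_only", "pump_co2")


@dataclass
class LockArena:
    """Rectangular lock chamber with an absorbing downstream gate line."""

    length: float = 51.82  # m, along x
    width: float = 11.12   # m, along y
    gate_x: float = 0.0    # x-coordinate of the open downstream gate

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0:
            raise ValidationError("arena dimensions must be positive")
        if not (0.0 <= self.gate_x <= self.length):
            raise ValidationError("gate_x must lie within [0, length]")


@dataclass
class TreatmentProfile:
    """Covariate profile of one trial.

    ``pump_on(t)`` and ``co2_mgL(t)`` are callables of time in seconds.
    CO2 ramps linearly from 0 to ``target_co2`` over ``ramp_s`` seconds and
    is then held (pump_co2 only); it is identically 0 otherwise.
    """

    treatment_label: str
    horizon_s: float
    temperature_C: float
    target_co2: float = 0.0
    ramp_s: float = 0.0

    def __post_init__(self):
        if self.treatment_label not in TREATMENTS:
            raise ValidationError(
                f"unknown treatment label {self.treatment_label!r}; "
                f"expected one of {TREATMENTS}"
            )
        if self.horizon_s <= 0:
            raise ValidationError("horizon_s must be positive")
        if self.target_co2 < 0:
            raise ValidationError("target_co2 must be nonnegative")

    def pump_on(self, t):
        t = np.asarray(t, dtype=float)
        on = (
            np.ones_like(t)
            if self.treatment_label in ("pump_only", "pump_co2")
            else np.zeros_like(t)
        )
        return on if on.ndim else float(on)

    def co2_mgL(self, t):
        t = np.asarray(t, dtype=float)
        if self.treatment_label != "pump_co2" or self.target_co2 == 0:
            out = np.zeros_like(t)
        else:
            out = self.target_co2 * np.clip(t / self.ramp_s, 0.0, 1.0)
        return out if out.ndim else float(out)

    def covariate_table(self, trial_id=None, dt_s: float = DT_S) -> pd.DataFrame:
        t = np.arange(0.0, self.horizon_s + dt_s / 2, dt_s)
        return pd.DataFrame(
            {
                "trial_id": trial_id,
                "t_s": t,
                "pump_on": self.pump_on(t).astype(int),
                "co2_mgL": self.co2_mgL(t),
                "temp_C": self.temperature_C,
            }
        )


def make_treatment_profile(
    label: str,
    horizon_s: float = 5400.0,
    ramp_minutes: float = 7.5,
    target_co2: float = 125.0,
    temperature: float = 22.0,
) -> TreatmentProfile:
    """Build a treatment covariate profile.

    Defaults follow the study protocol: 90-min trials, CO2 ramped to a
    target in the 100-150 mg/L range within 5-10 min, pumps on from gate
    opening for the two circulation treatments.
    """
    if label not in TREATMENTS:
        raise ValidationError(
            f"unknown treatment label {label!r}; expected one of {TREATMENTS}"
        )
    is_co2 = label == "pump_co2"
    return TreatmentProfile(
        treatment_label=label,
        horizon_s=float(horizon_s),
        temperature_C=float(temperature),
        target_co2=float(target_co2) if is_co2 else 0.0,
        ramp_s=float(ramp_minutes) * 60.0 if is_co2 else 0.0,
    )


@dataclass
class SimTruth:
    """Ground truth for one simulated fish."""

    fish_id: str
    state_sequence: np.ndarray      # per-step state, 1=exploratory 2=encamped
    true_params: HmmParams
    exit_time_s: float              # horizon if censored
    censored: bool
    t: np.ndarray                   # grid times of the true path nodes
    x: np.ndarray
    y: np.ndarray


@dataclass
class SimulatedTrial:
    """One trial's simulated fish plus its covariate profile."""

    trial_id: object
    arena: LockArena
    profile: TreatmentProfile
    fish: list  # of (FixSeries, SimTruth)


# ---------------------------------------------------------------------------
# study-calibrated defaults
# ---------------------------------------------------------------------------

_TRIALS = [3, 5, 7, 8, 9, 11, 13, 15, 16, 18, 20, 22, 23, 25, 27, 29, 30, 32, 34]

_TR12 = [-0.0022, -0.7357, 0.7245, 1.3874, -0.2170, 0.5541, 0.0836, 1.2704,
         1.7770, -0.0840, 0.8212, 0.0584, 1.0770, 1.0040, 0.5568, -0.0950,
         1.6406, 0.0796, -7.0871]
_TR21 = [1.5630, 1.2176, -0.1150, 1.4498, 1.5778, 1.2692, 0.8403, 1.6300,
         1.2854, 0.3666, -1.5633, 1.4563, 0.5765, 0.4858, -0.6091, 1.0060,
         0.0208, 0.8260, 11.5272]
_ST1 = [-0.1591, 0.1972, -0.1162, -0.2938, 0.0819, 0.1232, -0.1762, -0.2436,
        -0.4697, 0.0488, -0.1033, 0.1803, -0.1256, -0.2043, 0.1227, 0.1948,
        -0.4584, 0.3547, -0.2096]
_ST2 = [0.6082, 1.1703, -0.2302, -0.0974, 0.9923, 0.4183, 0.0872, -0.0655,
        -0.5593, -0.1504, -0.5408, 0.8814, -0.5767, -0.6236, -0.3080, -0.0547,
        -0.8583, 0.2255, -0.2432]


def study_default_params(include_trial_effects: bool = False) -> HmmParams:
    """Simulator ground-truth defaults calibrated to the field study.

    Coefficients are the fitted values from the navigation-lock carp
    experiment this package is built around: logit-scale switching
    coefficients, log-scale step-mean coefficients (per mg/L CO2, per deg C,
    pump-off indicator with pump on as reference, trial 1 as reference
    trial), log-scale step SDs, logit-scale zero masses, and near-uniform
    von Mises turning angles.
    """
    def trial_dict(vals):
        return dict(zip(_TRIALS, vals)) if include_trial_effects else {}

    trans = TransitionCoefficients(
        to_encamped=LinearCoefficients(
            intercept=-2.2094, trial=trial_dict(_TR12),
            pump_off=-1.3368, co2=0.0096, temp=0.0223,
        ),
        to_exploratory=LinearCoefficients(
            intercept=1.7924, trial=trial_dict(_TR21),
            pump_off=0.9893, co2=0.0010, temp=-0.2335,
        ),
    )
    step = StepCoefficients(
        mean=(
            LinearCoefficients(
                intercept=-1.6223, trial=trial_dict(_ST1),
                pump_off=0.1478, co2=-0.0014, temp=0.0662,
            ),
            LinearCoefficients(
                intercept=0.1986, trial=trial_dict(_ST2),
                pump_off=0.4132, co2=-0.0015, temp=-0.0847,
            ),
        ),
        log_sd=np.array([-0.07454863, -1.665357]),
        logit_zero_mass=np.array([-8.450786, -15.27187]),
    )
    angle = AngleParams(
        mu=np.array([-3.1414, -0.00008]), kappa=np.array([0.00002, 0.0009])
    )
    return HmmParams(transition=trans, step=step, angle=angle)


def study_roster() -> pd.DataFrame:
    """Trial roster of the field experiment: 20 trials, treatment, n fish."""
    rows = [
        (1, "pump_co2", 3), (3, "pump_co2", 3), (5, "pump_only", 3),
        (7, "pump_only", 3), (8, "pump_co2", 3), (9, "pump_co2", 2),
        (11, "pump_only", 3), (13, "pump_co2", 3), (15, "null", 3),
        (16, "pump_co2", 3), (18, "pump_only", 2), (20, "pump_only", 3),
        (22, "pump_co2", 3), (23, "pump_co2", 3), (25, "pump_only", 3),
        (27, "pump_co2", 3), (29, "null", 3), (30, "pump_co2", 3),
        (32, "pump_co2", 3), (34, "pump_co2", 2),
    ]
    return pd.DataFrame(rows, columns=["trial_id", "treatment", "n_fish"])


# ---------------------------------------------------------------------------
# movement simulation
# ---------------------------------------------------------------------------

def _fold_segment(x, y, heading, length_m, arena: LockArena):
    """Propagate a straight step of given length with wall reflections.

    Returns (x, y, heading, exited, traveled_fraction_at_exit). The gate
    line x = gate_x is absorbing; other walls reflect specularly.
    """
    remaining = length_m
    traveled = 0.0
    for _ in range(1000):
        cx, cy = np.cos(heading), np.sin(heading)
        hits = []
        if cx < 0:
            hits.append(((arena.gate_x - x) / cx, "gate"))
        elif cx > 0:
            hits.append(((arena.length - x) / cx, "xhi"))
        if cy < 0:
            hits.append(((0.0 - y) / cy, "ylo"))
        elif cy > 0:
            hits.append(((arena.width - y) / cy, "yhi"))
        t_hit, wall = min(
            ((t, w) for t, w in hits if t > 1e-12), default=(np.inf, None)
        )
        if t_hit >= remaining:
            return x + cx * remaining, y + cy * remaining, heading, False, 1.0
        x += cx * t_hit
        y += cy * t_hit
        traveled += t_hit
        remaining -= t_hit
        if wall == "gate":
            return x, y, heading, True, traveled / length_m
        if wall == "xhi":
            heading = wrap_angle(np.pi - heading)
        else:
            heading = wrap_angle(-heading)
    return x, y, heading, False, 1.0


def _switch_probs(params: HmmParams, trial_id, pump, co2, temp):
    psi12 = float(
        expit(params.transition.to_encamped.linear_predictor(trial_id, pump, co2, temp))
    )
    psi21 = float(
        expit(params.transition.to_exploratory.linear_predictor(trial_id, pump, co2, temp))
    )
    return psi12, psi21


def _draw_step(rng, params: HmmParams, k, trial_id, pump, co2, temp):
    """Draw (step length, turning angle) from state k's emissions (k in 0/1)."""
    p0 = params.step.zero_mass(k + 1)
    if rng.uniform() < p0:
        step = 0.0
    else:
        m = float(
            np.exp(
                params.step.mean[k].linear_predictor(trial_id, pump, co2, temp)
            )
        )
        s = params.step.sd(k + 1)
        shape = m * m / (s * s)
        step = float(rng.gamma(shape, s * s / m))
    angle = float(
        wrap_angle(
            rng.vonmises(float(params.angle.mu[k]), float(params.angle.kappa[k]))
        )
    )
    return step, angle


def simulate_trial(
    arena: LockArena,
    profile: TreatmentProfile,
    true_params: HmmParams,
    n_fish: int,
    seed: int,
    trial_id=1,
    dt_s: float = DT_S,
    fix_gap_range_s: tuple = PULSE_GAP_RANGE_S,
    noise_sd_m: float = POSITION_NOISE_SD_M,
) -> list:
    """Simulate one trial; returns a list of (FixSeries, SimTruth) per fish.

    Fish start uniformly in the upstream two-thirds of the chamber with a
    uniform initial heading and an initial state drawn from the stationary
    distribution at the opening-time covariates. A fish's series ends when
    it crosses the gate line or at the horizon. Identical seeds give
    byte-identical output.
    """
    if n_fish < 1:
        raise ValidationError("n_fish must be >= 1")
    if profile.horizon_s <= 0:
        raise ValidationError("horizon must be positive")

    rng = np.random.default_rng(seed)
    n_steps_max = int(np.floor(profile.horizon_s / dt_s))
    t_grid = dt_s * np.arange(n_steps_max + 1)
    pump = np.asarray(profile.pump_on(t_grid))
    co2 = np.asarray(profile.co2_mgL(t_grid))
    temp = profile.temperature_C

    out = []
    for i in range(n_fish):
        fish_id = f"T{trial_id}F{i + 1}"
        x = rng.uniform(arena.gate_x + (arena.length - arena.gate_x) / 3.0, arena.length)
        y = rng.uniform(0.0, arena.width)
        heading = rng.uniform(-np.pi, np.pi)
        psi12, psi21 = _switch_probs(true_params, trial_id, pump[0], co2[0], temp)
        p_exp = psi21 / (psi12 + psi21) if psi12 + psi21 > 0 else 0.5
        state = 0 if rng.uniform() < p_exp else 1

        xs, ys, ts = [x], [y], [0.0]
        states = []
        exited = False
        exit_time = float(profile.horizon_s)
        for k in range(n_steps_max):
            step, angle = _draw_step(
                rng, true_params, state, trial_id, pump[k], co2[k], temp
            )
            states.append(state + 1)
            if step > 0.0:
                heading = wrap_angle(heading + angle)
                x, y, heading, exited, frac = _fold_segment(
                    x, y, heading, step, arena
                )
            else:
                frac = 1.0
            if exited:
                exit_time = t_grid[k] + dt_s * frac
                xs.append(x)
                ys.append(y)
                ts.append(exit_time)
                break
            xs.append(x)
            ys.append(y)
            ts.append(t_grid[k + 1])
            psi12, psi21 = _switch_probs(
                true_params, trial_id, pump[k], co2[k], temp
            )
            p_switch = psi12 if state == 0 else psi21
            if rng.uniform() < p_switch:
                state = 1 - state

        truth = SimTruth(
            fish_id=fish_id,
            state_sequence=np.array(states, dtype=int),
            true_params=true_params,
            exit_time_s=exit_time,
            censored=not exited,
            t=np.array(ts),
            x=np.array(xs),
            y=np.array(ys),
        )

        end = exit_time if exited else float(profile.horizon_s)
        fix_t = [0.0]
        while True:
            nxt = fix_t[-1] + rng.uniform(*fix_gap_range_s)
            if nxt >= end:
                break
            fix_t.append(nxt)
        if end > fix_t[-1]:
            fix_t.append(end)
        fix_t = np.array(fix_t)
        fx = np.interp(fix_t, truth.t, truth.x) + rng.normal(0, noise_sd_m, len(fix_t))
        fy = np.interp(fix_t, truth.t, truth.y) + rng.normal(0, noise_sd_m, len(fix_t))
        fixes = FixSeries(fish_id=fish_id, t=fix_t, x=fx, y=fy, trial_id=trial_id)
        out.append((fixes, truth))
    return out


def simulate_step_series(
    true_params: HmmParams,
    profile: TreatmentProfile,
    n_steps: int,
    n_tracks: int,
    seed: int,
    trial_id=1,
    dt_s: float = DT_S,
):
    """Simulate step/angle series directly from the HMM (no spatial walls).

    Bypasses the arena mechanics, so the emitted step lengths and turning
    angles follow the state-dependent distributions exactly; used for
    parameter-recovery and residual-calibration studies. Returns
    (list of StepAngleSeries, list of true state arrays with labels 1/2).
    """
    if n_steps * dt_s > profile.horizon_s + dt_s:
        raise ValidationError("profile horizon shorter than requested steps")
    rng = np.random.default_rng(seed)
    t = dt_s * np.arange(n_steps)
    pump = np.asarray(profile.pump_on(t))
    co2 = np.asarray(profile.co2_mgL(t))
    temp = profile.temperature_C

    series, truths = [], []
    for i in range(n_tracks):
        steps = np.zeros(n_steps)
        angles = np.zeros(n_steps)
        states = np.zeros(n_steps, dtype=int)
        psi12, psi21 = _switch_probs(true_params, trial_id, pump[0], co2[0], temp)
        p_exp = psi21 / (psi12 + psi21) if psi12 + psi21 > 0 else 0.5
        k = 0 if rng.uniform() < p_exp else 1
        for j in range(n_steps):
            states[j] = k + 1
            steps[j], angles[j] = _draw_step(
                rng, true_params, k, trial_id, pump[j], co2[j], temp
            )
            if j < n_steps - 1:
                psi12, psi21 = _switch_probs(
                    true_params, trial_id, pump[j], co2[j], temp
                )
                if rng.uniform() < (psi12 if k == 0 else psi21):
                    k = 1 - k
        angles[0] = np.nan
        zero_adjacent = np.zeros(n_steps, dtype=bool)
        zero_adjacent[1:] = (steps[1:] == 0) | (steps[:-1] == 0)
        angles = np.where(zero_adjacent, np.nan, angles)
        series.append(
            StepAngleSeries(
                fish_id=f"S{i + 1}",
                trial_id=trial_id,
                t_s=t,
                step_m=steps,
                angle_rad=angles,
                pump_on=pump.astype(int),
                co2_mgL=co2,
                temp_C=np.full(n_steps, temp),
            )
        )
        truths.append(states)
    return series, truths


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def write_fixtures(trials, directory) -> dict:
    """Write fix, covariate, and truth tables plus a JSON manifest.

    ``trials`` is a nonempty list of :class:`SimulatedTrial`. Returns the
    manifest (also written to ``manifest.json``); all tables round-trip
    through :func:`read_fix_table` / :func:`read_covariate_table`.
    """
    trials = list(trials)
    if not trials:
        raise ValidationError("trials must be nonempty")
    directory = str(directory)
    try:
        os.makedirs(directory, exist_ok=True)
        probe = os.path.join(directory, ".write_probe")
        with open(probe, "w"):
            pass
        os.remove(probe)
    except OSError as e:
        raise ValidationError(f"directory {directory!r} is not writable: {e}")

    manifest = {"trials": []}
    for trial in trials:
        entry = {
            "trial_id": trial.trial_id,
            "treatment": trial.profile.treatment_label,
            "fix_files": [],
        }
        cov_path = os.path.join(directory, f"covariates_trial{trial.trial_id}.csv")
        trial.profile.covariate_table(trial_id=trial.trial_id).to_csv(
            cov_path, index=False
        )
        entry["covariate_file"] = os.path.basename(cov_path)

        truth_rows = []
        for fixes, truth in trial.fish:
            fix_path = os.path.join(
                directory, f"fixes_trial{trial.trial_id}_{fixes.fish_id}.csv"
            )
            fixes.to_frame().to_csv(fix_path, index=False)
            entry["fix_files"].append(os.path.basename(fix_path))
            truth_rows.append(
                pd.DataFrame(
                    {
                        "fish_id": truth.fish_id,
                        "step_index": np.arange(len(truth.state_sequence)),
                        "state": truth.state_sequence,
                        "exit_time_s": truth.exit_time_s,
                        "censored": int(truth.censored),
                    }
                )
            )
        truth_path = os.path.join(directory, f"truth_trial{trial.trial_id}.csv")
        pd.concat(truth_rows, ignore_index=True).to_csv(truth_path, index=False)
        entry["truth_file"] = os.path.basename(truth_path)
        manifest["trials"].append(entry)

    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def read_fix_table(path) -> FixSeries:
    return FixSeries.from_frame(pd.read_csv(path))


def read_covariate_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
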