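"""Two-state covariate-driven hidden Markov model for fish movement.

States are behavioral: state 1 "exploratory" (long steps, diffuse turning)
and state 2 "encamped" (short, directionally persistent steps). Observations
per 6-s step are (step length, turning angle). Emissions:

* step length | state k: zero-inflated gamma. With probability
  p0_k = logistic(zero-mass parameter) the step is exactly 0 (stationary
  fix); otherwise gamma with mean m = exp(linear predictor in trial, pump,
  CO2 and temperature covariates) and SD s = exp(log-SD parameter),
  parameterized as shape = m^2/s^2, scale = s^2/m.
* turning angle | state k: von Mises(mu_k, kappa_k); the first step of a
  track and steps adjacent to a zero-length step have no defined angle and
  contribute a factor of 1.

Switching probabilities psi_{1->2}, psi_{2->1} are logistic in the same
covariates (a two-state multinomial logit), evaluated per step, so the
transition matrix is time-varying. The initial state distribution defaults
to the stationary distribution of the transition matrix at each fish's
first-step covariates.

Fitting maximizes the forward-algorithm likelihood over all working-scale
parameters by quasi-Newton with seeded random restarts; the label-switching
ambiguity is resolved post hoc by calling the state with the larger fitted
mean step "exploratory". Standard errors come from the inverse observed
information (numerically differentiated Hessian).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammainc, gammaln, i0e, logit, ndtri
from scipy.stats import vonmises

from . import _kernels
from .errors import FitError, ValidationError
from .regularize import StepAngleSeries, wrap_angle

__all__ = [
    "LinearCoefficients",
    "TransitionCoefficients",
    "StepCoefficients",
    "AngleParams",
    "HmmParams",
    "HmmDesign",
    "FitOptions",
    "FitResult",
    "Decoding",
    "transition_matrix",
    "step_density",
    "angle_density",
    "loglik_forward",
    "fit_hmm",
    "viterbi",
    "state_probabilities",
    "decode",
    "state_time_budget",
    "pseudo_residuals",
]

EXPLORATORY, ENCAMPED = 1, 2  # public state labels; internal indices 0, 1


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class LinearCoefficients:
    """Coefficients of one linear predictor (logit or log working scale).

    ``trial`` maps trial labels to effects; the reference trial (effect 0)
    is ``reference_trial`` when set, otherwise any label absent from
    ``trial`` is treated as reference.
    """

    intercept: float = 0.0
    trial: dict = field(default_factory=dict)
    pump_off: float = 0.0   # indicator 1 - pump_on; reference = pump on
    co2: float = 0.0        # per mg/L
    temp: float = 0.0       # per degree C

    def trial_effect(self, trial_id) -> float:
        if trial_id in self.trial:
            return self.trial[trial_id]
        ref = getattr(self, "reference_trial", None)
        if self.trial and ref is not None and trial_id != ref:
            raise ValidationError(f"unknown trial level {trial_id!r}")
        return 0.0

    def linear_predictor(self, trial_id, pump_on, co2_mgL, temp_C):
        """Evaluate eta; pump_on/co2/temp may be scalars or arrays."""
        pump_on = np.asarray(pump_on, dtype=float)
        return (
            self.intercept
            + self.trial_effect(trial_id)
            + self.pump_off * (1.0 - pump_on)
            + self.co2 * np.asarray(co2_mgL, dtype=float)
            + self.temp * np.asarray(temp_C, dtype=float)
        )


@dataclass
class TransitionCoefficients:
    """Logit-scale coefficients for the two switching probabilities."""

    to_encamped: LinearCoefficients      # state 1 -> 2
    to_exploratory: LinearCoefficients   # state 2 -> 1


@dataclass
class StepCoefficients:
    """Step-length emission parameters per state (1=exploratory, 2=encamped).

    ``mean`` holds log-scale coefficients of the gamma mean; ``log_sd`` and
    ``logit_zero_mass`` are single covariate-free working parameters per
    state.
    """

    mean: tuple  # (LinearCoefficients, LinearCoefficients)
    log_sd: np.ndarray
    logit_zero_mass: np.ndarray

    def __post_init__(self):
        self.log_sd = np.asarray(self.log_sd, dtype=float)
        self.logit_zero_mass = np.asarray(self.logit_zero_mass, dtype=float)
        if not np.all(np.isfinite(self.log_sd)):
            raise ValidationError("log_sd must be finite")

    def sd(self, k: int) -> float:
        return float(np.exp(self.log_sd[k - 1]))

    def zero_mass(self, k: int) -> float:
        return float(expit(self.logit_zero_mass[k - 1]))


@dataclass
class AngleParams:
    """von Mises turning-angle parameters per state."""

    mu: np.ndarray     # radians in (-pi, pi]
    kappa: np.ndarray  # concentration >= 0

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if np.any(self.kappa < 0):
            raise ValidationError("kappa must be nonnegative")


@dataclass
class HmmParams:
    """Complete parameter set of the two-state movement HMM."""

    transition: TransitionCoefficients
    step: StepCoefficients
    angle: AngleParams
    delta: np.ndarray | None = None  # initial distribution; None = stationary

    def __post_init__(self):
        if self.delta is not None:
            self.delta = np.asarray(self.delta, dtype=float)
            if self.delta.shape != (2,) or np.any(self.delta < 0) or not np.isclose(
                self.delta.sum(), 1.0
            ):
                raise ValidationError("delta must be two probabilities summing to 1")


# ---------------------------------------------------------------------------
# elementary densities and link evaluations
# ---------------------------------------------------------------------------

def transition_matrix(coef: TransitionCoefficients, covariates_at_t) -> np.ndarray:
    """2x2 stochastic matrix at one covariate setting.

    ``covariates_at_t`` is a mapping with keys trial_id, pump_on, co2_mgL,
    temp_C. Rows index the current state (exploratory, encamped); each row
    sums to 1 by construction.
    """
    c = covariates_at_t
    psi12 = float(
        expit(
            coef.to_encamped.linear_predictor(
                c.get("trial_id"), c["pump_on"], c["co2_mgL"], c["temp_C"]
            )
        )
    )
    psi21 = float(
        expit(
            coef.to_exploratory.linear_predictor(
                c.get("trial_id"), c["pump_on"], c["co2_mgL"], c["temp_C"]
            )
        )
    )
    return np.array([[1.0 - psi12, psi12], [psi21, 1.0 - psi21]])


def gamma_shape_scale(mean: float, sd: float) -> tuple:
    """Moment-matching parameterization: shape = m^2/s^2, scale = s^2/m."""
    return mean * mean / (sd * sd), sd * sd / mean


def step_density(step_m: float, state: int, coef: StepCoefficients, covariates) -> float:
    """Zero-inflated gamma density of one step length in state ``state``.

    Returns the point mass p0 at step_m == 0, else (1 - p0) times the gamma
    pdf with covariate-dependent mean and state-specific SD.
    """
    if step_m < 0:
        raise ValidationError("step length must be nonnegative")
    k = state - 1
    c = covariates
    m = float(
        np.exp(
            coef.mean[k].linear_predictor(
                c.get("trial_id"), c["pump_on"], c["co2_mgL"], c["temp_C"]
            )
        )
    )
    s = coef.sd(state)
    p0 = coef.zero_mass(state)
    if step_m == 0.0:
        return p0
    a, sc = gamma_shape_scale(m, s)
    logpdf = (a - 1.0) * math.log(step_m) - step_m / sc - gammaln(a) - a * math.log(sc)
    return (1.0 - p0) * math.exp(logpdf)


def angle_density(angle_rad, state: int, params: AngleParams) -> float:
    """von Mises density; a missing (NaN) angle contributes a factor of 1."""
    k = state - 1
    kappa = float(params.kappa[k])
    if kappa < 0:
        raise ValidationError("kappa must be nonnegative")
    if angle_rad is None or (isinstance(angle_rad, float) and math.isnan(angle_rad)):
        return 1.0
    mu = float(params.mu[k])
    # exp(kappa cos(phi-mu)) / (2 pi I0(kappa)), via exponentially scaled I0
    return math.exp(kappa * (math.cos(angle_rad - mu) - 1.0)) / (
        2.0 * math.pi * i0e(kappa)
    )


# ---------------------------------------------------------------------------
# vectorized emission / transition machinery
# ---------------------------------------------------------------------------

def _step_logdens_vec(steps, mean, sd, p0):
    """Vectorized zero-inflated gamma log-density. ``mean`` per-step array."""
    steps = np.asarray(steps, dtype=float)
    mean = np.broadcast_to(np.asarray(mean, dtype=float), steps.shape)
    a = mean * mean / (sd * sd)
    sc = sd * sd / mean
    out = np.full(steps.shape, -np.inf)
    pos = steps > 0
    sp = steps[pos]
    out[pos] = (
        np.log1p(-p0)
        + (a[pos] - 1.0) * np.log(sp)
        - sp / sc[pos]
        - gammaln(a[pos])
        - a[pos] * np.log(sc[pos])
    )
    if p0 > 0:
        out[~pos] = np.log(p0)
    return out


def _angle_logdens_vec(angles, mu, kappa):
    angles = np.asarray(angles, dtype=float)
    out = np.zeros(angles.shape)
    ok = np.isfinite(angles)
    out[ok] = kappa * (np.cos(angles[ok] - mu) - 1.0) - np.log(
        2.0 * np.pi * i0e(kappa)
    )
    return out


def _series_arrays(params: HmmParams, series: StepAngleSeries):
    """Per-fish (delta, psi12, psi21, b) arrays for the recursions."""
    s = series
    if np.any(~np.isfinite(s.co2_mgL)) or np.any(~np.isfinite(s.temp_C)):
        bad = int(
            np.flatnonzero(~np.isfinite(s.co2_mgL) | ~np.isfinite(s.temp_C))[0]
        )
        raise ValidationError(
            f"NaN covariate for fish {s.fish_id} at step {bad}"
        )
    tr = params.transition
    psi12 = expit(
        tr.to_encamped.linear_predictor(s.trial_id, s.pump_on, s.co2_mgL, s.temp_C)
    )
    psi21 = expit(
        tr.to_exploratory.linear_predictor(s.trial_id, s.pump_on, s.co2_mgL, s.temp_C)
    )
    psi12 = np.atleast_1d(np.asarray(psi12, dtype=float))
    psi21 = np.atleast_1d(np.asarray(psi21, dtype=float))

    T = len(s)
    logb = np.zeros((T, 2))
    for k in (0, 1):
        m = np.exp(
            params.step.mean[k].linear_predictor(
                s.trial_id, s.pump_on, s.co2_mgL, s.temp_C
            )
        )
        logb[:, k] = _step_logdens_vec(
            s.step_m, m, params.step.sd(k + 1), params.step.zero_mass(k + 1)
        ) + _angle_logdens_vec(
            s.angle_rad, float(params.angle.mu[k]), float(params.angle.kappa[k])
        )
    b = np.exp(np.clip(logb, -700, 700))

    if params.delta is not None:
        delta = params.delta
    else:
        denom = psi12[0] + psi21[0]
        p1 = psi21[0] / denom if denom > 0 else 0.5
        delta = np.array([p1, 1.0 - p1])
    return delta, psi12, psi21, b


def loglik_forward(params: HmmParams, data) -> float:
    """Forward-algorithm log-likelihood summed over independent fish."""
    data = _as_series_list(data)
    if not data:
        raise ValidationError("data must contain at least one series")
    ll = 0.0
    for s in data:
        delta, psi12, psi21, b = _series_arrays(params, s)
        ll += float(
            _kernels.forward_ll(delta[0], delta[1], psi12, psi21, b)
        )
    return ll


def _as_series_list(data):
    if isinstance(data, StepAngleSeries):
        return [data]
    return list(data)


# ---------------------------------------------------------------------------
# design matrices and parameter packing for fitting
# ---------------------------------------------------------------------------

_VALID_TERMS = ("trial", "pump", "co2", "temp")


@dataclass
class HmmDesign:
    """Which covariates enter the transition and step-mean predictors."""

    transition_terms: tuple = ()
    step_terms: tuple = ()
    estimate_delta: bool = False

    def __post_init__(self):
        for t in tuple(self.transition_terms) + tuple(self.step_terms):
            if t not in _VALID_TERMS:
                raise ValidationError(
                    f"unknown design term {t!r}; valid terms: {_VALID_TERMS}"
                )


@dataclass
class FitOptions:
    n_restarts: int = 5
    seed: int = 0
    maxiter: int = 500
    tol: float = 1e-8       # relative log-likelihood convergence tolerance
    compute_se: bool = True


class _Design:
    """Concrete design matrices built from the data, with standardization.

    Continuous covariates (CO2, temperature) are centered and scaled for
    optimization; coefficients and their covariance are mapped back to the
    natural scale afterwards.
    """

    def __init__(self, data, design: HmmDesign):
        self.spec = design
        self.trial_levels = sorted({s.trial_id for s in data}, key=str)
        self.reference_trial = self.trial_levels[0]

        cols = {}
        n_tot = sum(len(s) for s in data)
        co2 = np.concatenate([s.co2_mgL for s in data])
        temp = np.concatenate([s.temp_C for s in data])
        self.scale = {
            "co2": (float(co2.mean()), float(co2.std()) or 1.0),
            "temp": (float(temp.mean()), float(temp.std()) or 1.0),
        }

        def build(terms):
            names = ["intercept"]
            blocks = [np.ones((n_tot, 1))]
            for term in terms:
                if term == "trial":
                    tri = np.concatenate(
                        [np.full(len(s), 0) + self.trial_levels.index(s.trial_id) for s in data]
                    )
                    for lev in self.trial_levels[1:]:
                        names.append(f"trial[{lev}]")
                        blocks.append(
                            (tri == self.trial_levels.index(lev)).astype(float)[:, None]
                        )
                elif term == "pump":
                    po = np.concatenate([1.0 - s.pump_on for s in data])
                    names.append("pump_off")
                    blocks.append(po[:, None])
                elif term == "co2":
                    m, sd = self.scale["co2"]
                    names.append("co2")
                    blocks.append(((co2 - m) / sd)[:, None])
                elif term == "temp":
                    m, sd = self.scale["temp"]
                    names.append("temp")
                    blocks.append(((temp - m) / sd)[:, None])
            return names, np.hstack(blocks)

        self.tr_names, self.X_tr = build(design.transition_terms)
        self.st_names, self.X_st = build(design.step_terms)
        self.starts = np.concatenate(
            [[0], np.cumsum([len(s) for s in data])]
        ).astype(int)

    # -- natural-scale back-transform -------------------------------------
    def _block_transform(self, names):
        """Matrix A with natural = A @ standardized for one predictor."""
        p = len(names)
        A = np.eye(p)
        for j, nm in enumerate(names):
            if nm in ("co2", "temp"):
                m, sd = self.scale[nm]
                A[j, j] = 1.0 / sd
                A[0, j] = -m / sd
        return A

    def natural_coefs(self, std_vec, names):
        return self._block_transform(names) @ std_vec

    def to_linear_coefficients(self, std_vec, names) -> LinearCoefficients:
        nat = self.natural_coefs(std_vec, names)
        lc = LinearCoefficients(intercept=float(nat[0]))
        for j, nm in enumerate(names[1:], start=1):
            if nm.startswith("trial["):
                lc.trial[_parse_trial(nm, self.trial_levels)] = float(nat[j])
            elif nm == "pump_off":
                lc.pump_off = float(nat[j])
            elif nm == "co2":
                lc.co2 = float(nat[j])
            elif nm == "temp":
                lc.temp = float(nat[j])
        lc.reference_trial = self.reference_trial if lc.trial else None
        return lc


def _parse_trial(name, levels):
    inner = name[len("trial["):-1]
    for lev in levels:
        if str(lev) == inner:
            return lev
    return inner


class _Packer:
    """Maps between the flat working vector and parameter blocks."""

    def __init__(self, design: _Design, estimate_delta: bool):
        p_tr = len(design.tr_names)
        p_st = len(design.st_names)
        self.p_tr, self.p_st = p_tr, p_st
        self.estimate_delta = estimate_delta
        self.slices = {}
        off = 0
        for name, size in [
            ("b12", p_tr),
            ("b21", p_tr),
            ("th1", p_st),
            ("th2", p_st),
            ("log_sd", 2),
            ("zm", 2),
            ("mu", 2),
            ("log_kappa", 2),
        ]:
            self.slices[name] = slice(off, off + size)
            off += size
        if estimate_delta:
            self.slices["delta_logit"] = slice(off, off + 1)
            off += 1
        self.size = off

    def bounds(self):
        b = []
        for name, sl in self.slices.items():
            n = sl.stop - sl.start
            if name in ("b12", "b21", "th1", "th2"):
                b += [(-30.0, 30.0)] * n
            elif name == "log_sd":
                b += [(-10.0, 5.0)] * n
            elif name == "zm":
                b += [(-25.0, 5.0)] * n
            elif name == "mu":
                b += [(-7.0, 7.0)] * n
            elif name == "log_kappa":
                b += [(-12.0, 5.0)] * n
            else:
                b += [(-10.0, 10.0)] * n
        return b

    def names(self, design: _Design):
        out = []
        for nm in design.tr_names:
            out.append(f"psi[1->2].{nm}")
        for nm in design.tr_names:
            out.append(f"psi[2->1].{nm}")
        for nm in design.st_names:
            out.append(f"step_mean[exploratory].{nm}")
        for nm in design.st_names:
            out.append(f"step_mean[encamped].{nm}")
        out += [
            "log_sd[exploratory]",
            "log_sd[encamped]",
            "zero_mass[exploratory]",
            "zero_mass[encamped]",
            "angle_mu[exploratory]",
            "angle_mu[encamped]",
            "log_kappa[exploratory]",
            "log_kappa[encamped]",
        ]
        if self.estimate_delta:
            out.append("delta_logit[exploratory]")
        return out


def _objective_factory(design: _Design, packer: _Packer, steps, angles):
    """Negative log-likelihood over the working vector; all-numpy + kernels."""
    X_tr, X_st, starts = design.X_tr, design.X_st, design.starts
    n_fish = len(starts) - 1
    sl = packer.slices

    log_steps = np.where(steps > 0, np.log(np.where(steps > 0, steps, 1.0)), 0.0)
    pos = steps > 0
    ang_ok = np.isfinite(angles)
    ang = np.where(ang_ok, angles, 0.0)

    def negll(theta):
        eta12 = X_tr @ theta[sl["b12"]]
        eta21 = X_tr @ theta[sl["b21"]]
        psi12 = expit(eta12)
        psi21 = expit(eta21)
        log_sd = theta[sl["log_sd"]]
        zm = theta[sl["zm"]]
        mu = theta[sl["mu"]]
        kappa = np.exp(theta[sl["log_kappa"]])
        p0 = expit(zm)

        logb = np.empty((len(steps), 2))
        for k, th_name in enumerate(("th1", "th2")):
            lm = X_st @ theta[sl[th_name]]
            sd = np.exp(log_sd[k])
            a = np.exp(2.0 * (lm - log_sd[k]))        # m^2 / s^2
            log_sc = 2.0 * log_sd[k] - lm             # log(s^2 / m)
            lb = np.where(
                pos,
                np.log1p(-p0[k])
                + (a - 1.0) * log_steps
                - steps * np.exp(-log_sc)
                - gammaln(a)
                - a * log_sc,
                np.log(p0[k]) if p0[k] > 0 else -np.inf,
            )
            lb = lb + np.where(
                ang_ok,
                kappa[k] * (np.cos(ang - mu[k]) - 1.0)
                - np.log(2.0 * np.pi * i0e(kappa[k])),
                0.0,
            )
            logb[:, k] = lb
        b = np.exp(np.clip(logb, -700.0, 700.0))

        ll = 0.0
        for f in range(n_fish):
            i0, i1 = starts[f], starts[f + 1]
            if packer.estimate_delta:
                d0 = float(expit(theta[sl["delta_logit"]][0]))
            else:
                denom = psi12[i0] + psi21[i0]
                d0 = float(psi21[i0] / denom) if denom > 0 else 0.5
            llf = _kernels.forward_ll(
                d0, 1.0 - d0, psi12[i0:i1], psi21[i0:i1], b[i0:i1]
            )
            ll += llf
        if not np.isfinite(ll):
            return 1e10
        return -ll

    return negll


def _initial_theta(packer: _Packer, steps, zero_frac):
    theta = np.zeros(packer.size)
    sl = packer.slices
    pos = steps[steps > 0]
    if len(pos) >= 2:
        med = np.median(pos)
        hi = pos[pos > med]
        lo = pos[pos <= med]
        m_hi = float(hi.mean()) if len(hi) else float(pos.mean()) * 2
        m_lo = float(lo.mean()) if len(lo) else float(pos.mean()) / 2
        s_hi = float(hi.std()) if len(hi) > 1 else m_hi
        s_lo = float(lo.std()) if len(lo) > 1 else m_lo
    else:
        m_hi, m_lo, s_hi, s_lo = 1.0, 0.05, 1.0, 0.05
    theta[sl["th1"]][0] = np.log(max(m_hi, 1e-6))
    theta[sl["th2"]][0] = np.log(max(m_lo, 1e-6))
    theta[sl["log_sd"]] = np.log([max(s_hi, 1e-4), max(s_lo, 1e-4)])
    theta[sl["zm"]] = logit(np.clip(zero_frac if zero_frac > 0 else 1e-8, 1e-8, 0.5))
    theta[sl["b12"]][0] = logit(0.1)
    theta[sl["b21"]][0] = logit(0.1)
    theta[sl["mu"]] = 0.0
    theta[sl["log_kappa"]] = np.log(0.5)
    return theta


def _unpack_params(theta, design: _Design, packer: _Packer) -> HmmParams:
    sl = packer.slices
    trans = TransitionCoefficients(
        to_encamped=design.to_linear_coefficients(theta[sl["b12"]], design.tr_names),
        to_exploratory=design.to_linear_coefficients(theta[sl["b21"]], design.tr_names),
    )
    step = StepCoefficients(
        mean=(
            design.to_linear_coefficients(theta[sl["th1"]], design.st_names),
            design.to_linear_coefficients(theta[sl["th2"]], design.st_names),
        ),
        log_sd=theta[sl["log_sd"]].copy(),
        logit_zero_mass=theta[sl["zm"]].copy(),
    )
    angle = AngleParams(
        mu=wrap_angle(theta[sl["mu"]].copy()),
        kappa=np.exp(theta[sl["log_kappa"]].copy()),
    )
    delta = None
    if packer.estimate_delta:
        d0 = float(expit(theta[sl["delta_logit"]][0]))
        delta = np.array([d0, 1.0 - d0])
    return HmmParams(transition=trans, step=step, angle=angle, delta=delta)


def _swap_states_theta(theta, packer: _Packer):
    """Relabel states 1 <-> 2 in the working vector."""
    sl = packer.slices
    out = theta.copy()
    out[sl["b12"]], out[sl["b21"]] = theta[sl["b21"]].copy(), theta[sl["b12"]].copy()
    out[sl["th1"]], out[sl["th2"]] = theta[sl["th2"]].copy(), theta[sl["th1"]].copy()
    for nm in ("log_sd", "zm", "mu", "log_kappa"):
        out[sl[nm]] = theta[sl[nm]][::-1].copy()
    if packer.estimate_delta:
        out[sl["delta_logit"]] = -theta[sl["delta_logit"]]
    return out


@dataclass
class FitResult:
    """Fitted HMM with natural-scale coefficient table and diagnostics."""

    params_hat: HmmParams
    loglik: float
    n_obs: int
    convergence: bool
    se: pd.Series | None
    n_restarts_used: int
    coef_table: pd.DataFrame | None = None
    cov: np.ndarray | None = None  # natural-scale coefficient covariance

    def wald_ci(self, level: float = 0.95) -> pd.DataFrame:
        from scipy.stats import norm

        if self.coef_table is None or self.se is None:
            raise ValidationError("standard errors were not computed")
        z = norm.ppf(0.5 + level / 2.0)
        out = self.coef_table.copy()
        out["lo"] = out["estimate"] - z * out["se"]
        out["hi"] = out["estimate"] + z * out["se"]
        return out


def fit_hmm(data, design_spec: HmmDesign | None = None, options: FitOptions | None = None) -> FitResult:
    """Maximum-likelihood fit of the two-state movement HMM.

    ``design_spec`` selects which covariates enter the transition and
    step-mean linear predictors. Restarts perturb a moment-based start;
    after optimization states are ordered so state 1 (exploratory) has the
    larger fitted mean step.
    """
    data = _as_series_list(data)
    if not data:
        raise ValidationError("data must contain at least one series")
    design_spec = design_spec or HmmDesign()
    options = options or FitOptions()

    design = _Design(data, design_spec)
    packer = _Packer(design, design_spec.estimate_delta)
    steps = np.concatenate([s.step_m for s in data])
    angles = np.concatenate([s.angle_rad for s in data])
    negll = _objective_factory(design, packer, steps, angles)

    zero_frac = float(np.mean(steps == 0.0))
    theta0 = _initial_theta(packer, steps, zero_frac)
    bounds = packer.bounds()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    rng = np.random.default_rng(options.seed)
    best = None
    n_ok = 0
    for r in range(max(1, options.n_restarts)):
        start = theta0 if r == 0 else np.clip(
            theta0 + rng.normal(0.0, 0.4, size=packer.size), lo, hi
        )
        res = minimize(
            negll,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": options.maxiter, "ftol": options.tol},
        )
        if res.success:
            n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e10:
        raise FitError("all HMM restarts failed to converge", best_params=None)
    if n_ok == 0:
        raise FitError(
            "all HMM restarts reported non-convergence",
            best_params=_unpack_params(best.x, design, packer),
        )

    theta_hat = best.x
    # order states: exploratory = larger fitted mean step over the data
    sl = packer.slices
    mean1 = float(np.mean(np.exp(design.X_st @ theta_hat[sl["th1"]])))
    mean2 = float(np.mean(np.exp(design.X_st @ theta_hat[sl["th2"]])))
    if mean2 > mean1:
        theta_hat = _swap_states_theta(theta_hat, packer)

    params_hat = _unpack_params(theta_hat, design, packer)
    names = packer.names(design)

    A = _natural_transform(design, packer)
    nat_est = A @ theta_hat
    se = None
    cov_nat = None
    se_vals = np.full(packer.size, np.nan)
    if options.compute_se:
        from statsmodels.tools.numdiff import approx_hess1

        H = approx_hess1(theta_hat, negll)
        cov_std = np.linalg.pinv(H)
        cov_nat = A @ cov_std @ A.T
        se_vals = np.sqrt(np.clip(np.diag(cov_nat), 0.0, None))
        se = pd.Series(se_vals, index=names)
    coef_table = pd.DataFrame(
        {"name": names, "estimate": nat_est, "se": se_vals}
    )

    return FitResult(
        params_hat=params_hat,
        loglik=float(-best.fun),
        n_obs=int(len(steps)),
        convergence=bool(n_ok > 0),
        se=se,
        n_restarts_used=max(1, options.n_restarts),
        coef_table=coef_table,
        cov=cov_nat,
    )


def _natural_transform(design: _Design, packer: _Packer) -> np.ndarray:
    """Block-diagonal map from working to natural-scale coefficients."""
    A = np.eye(packer.size)
    sl = packer.slices
    A_tr = design._block_transform(design.tr_names)
    A_st = design._block_transform(design.st_names)
    for name, blk in [("b12", A_tr), ("b21", A_tr), ("th1", A_st), ("th2", A_st)]:
        s = sl[name]
        A[s, s] = blk
    return A


# ---------------------------------------------------------------------------
# decoding and diagnostics
# ---------------------------------------------------------------------------

@dataclass
class Decoding:
    """Decoded states for one fish."""

    fish_id: str
    viterbi_states: np.ndarray      # labels 1 (exploratory) / 2 (encamped)
    posterior_prob: np.ndarray      # P(state = exploratory) per step
    budget: float                   # fraction of Viterbi steps exploratory


def viterbi(params: HmmParams, data):
    """Jointly most probable state path per fish (labels 1/2)."""
    data = _as_series_list(data)
    paths = []
    for s in data:
        if len(s) == 0:
            raise ValidationError(f"empty series for fish {s.fish_id}")
        delta, psi12, psi21, b = _series_arrays(params, s)
        path = _kernels.viterbi_path(delta[0], delta[1], psi12, psi21, b)
        paths.append(np.asarray(path) + 1)
    return paths


def state_probabilities(params: HmmParams, data):
    """Forward-backward posterior P(state | all data) per fish, (T, 2)."""
    data = _as_series_list(data)
    out = []
    for s in data:
        if len(s) == 0:
            raise ValidationError(f"empty series for fish {s.fish_id}")
        delta, psi12, psi21, b = _series_arrays(params, s)
        alpha, _ = _kernels.forward_alphas(delta[0], delta[1], psi12, psi21, b)
        beta = _kernels.backward_betas(psi12, psi21, b)
        post = alpha * beta
        post /= post.sum(axis=1, keepdims=True)
        out.append(post)
    return out


def decode(params: HmmParams, data):
    """Viterbi path, posterior probabilities, and time budget per fish."""
    data = _as_series_list(data)
    paths = viterbi(params, data)
    posts = state_probabilities(params, data)
    out = []
    for s, path, post in zip(data, paths, posts):
        out.append(
            Decoding(
                fish_id=s.fish_id,
                viterbi_states=path,
                posterior_prob=post[:, 0],
                budget=float(np.mean(path == EXPLORATORY)),
            )
        )
    return out


def state_time_budget(decodings, exit_times, horizon_min: float = 90.0):
    """Per-fish exploratory-state time budgets paired with exit times.

    ``decodings`` maps fish id to :class:`Decoding`; ``exit_times`` maps
    fish id to (time_min, event) pairs or objects with ``time_min`` /
    ``event`` attributes. Censored fish are assigned the horizon as exit
    time. Returns (per-fish DataFrame, overall pooled exploratory fraction).
    """
    rows = []
    n_exp = 0
    n_all = 0
    for fish_id, dec in decodings.items():
        if len(dec.viterbi_states) == 0:
            raise ValidationError(f"no decoded steps for fish {fish_id}")
        if fish_id not in exit_times:
            raise ValidationError(f"missing exit record for fish {fish_id}")
        rec = exit_times[fish_id]
        if hasattr(rec, "time_min"):
            time_min, event = float(rec.time_min), int(rec.event)
        else:
            time_min, event = float(rec[0]), int(rec[1])
        if event == 0:
            time_min = horizon_min
        n_exp += int(np.sum(dec.viterbi_states == EXPLORATORY))
        n_all += len(dec.viterbi_states)
        rows.append(
            {
                "fish_id": fish_id,
                "fraction_exploratory": dec.budget,
                "exit_time_min": time_min,
                "exited": event,
            }
        )
    overall = n_exp / n_all
    return pd.DataFrame(rows), overall


def params_to_dict(params: HmmParams) -> dict:
    """JSON-serializable representation of :class:`HmmParams`."""

    def lc(c: LinearCoefficients):
        return {
            "intercept": c.intercept,
            "trial": {str(k): v for k, v in c.trial.items()},
            "pump_off": c.pump_off,
            "co2": c.co2,
            "temp": c.temp,
            "reference_trial": getattr(c, "reference_trial", None),
        }

    return {
        "transition": {
            "to_encamped": lc(params.transition.to_encamped),
            "to_exploratory": lc(params.transition.to_exploratory),
        },
        "step": {
            "mean": [lc(params.step.mean[0]), lc(params.step.mean[1])],
            "log_sd": params.step.log_sd.tolist(),
            "logit_zero_mass": params.step.logit_zero_mass.tolist(),
        },
        "angle": {
            "mu": params.angle.mu.tolist(),
            "kappa": params.angle.kappa.tolist(),
        },
        "delta": None if params.delta is None else params.delta.tolist(),
    }


def params_from_dict(d: dict) -> HmmParams:
    """Inverse of :func:`params_to_dict`. Trial keys parse back to int when
    possible (JSON object keys are strings)."""

    def key(k):
        try:
            return int(k)
        except (TypeError, ValueError):
            return k

    def lc(dd):
        c = LinearCoefficients(
            intercept=float(dd["intercept"]),
            trial={key(k): float(v) for k, v in dd.get("trial", {}).items()},
            pump_off=float(dd.get("pump_off", 0.0)),
            co2=float(dd.get("co2", 0.0)),
            temp=float(dd.get("temp", 0.0)),
        )
        ref = dd.get("reference_trial")
        if ref is not None:
            c.reference_trial = key(ref)
        return c

    return HmmParams(
        transition=TransitionCoefficients(
            to_encamped=lc(d["transition"]["to_encamped"]),
            to_exploratory=lc(d["transition"]["to_exploratory"]),
        ),
        step=StepCoefficients(
            mean=(lc(d["step"]["mean"][0]), lc(d["step"]["mean"][1])),
            log_sd=np.asarray(d["step"]["log_sd"], dtype=float),
            logit_zero_mass=np.asarray(d["step"]["logit_zero_mass"], dtype=float),
        ),
        angle=AngleParams(
            mu=np.asarray(d["angle"]["mu"], dtype=float),
            kappa=np.asarray(d["angle"]["kappa"], dtype=float),
        ),
        delta=None if d.get("delta") is None else np.asarray(d["delta"], dtype=float),
    )


def _vm_cdf_from_minus_pi(phi, mu, kappa):
    """von Mises CDF measured from -pi, for phi in (-pi, pi]."""
    if kappa == 0.0:
        return (np.asarray(phi) + np.pi) / (2.0 * np.pi)
    a = vonmises.cdf(wrap_angle(np.asarray(phi) - mu), kappa)
    b = vonmises.cdf(wrap_angle(-np.pi - mu), kappa)
    return np.mod(a - b, 1.0)


def pseudo_residuals(params: HmmParams, data) -> pd.DataFrame:
    """One-step-ahead (forecast) pseudo-residuals for steps and angles.

    z = Phi^{-1}(F(observation | past)), with F the state-conditional CDFs
    mixed by forward-predictive weights. Under a correctly specified model
    the residuals are approximately standard normal. Angle residuals are
    NaN where the angle is undefined.
    """
    data = _as_series_list(data)
    frames = []
    for s in data:
        delta, psi12, psi21, b = _series_arrays(params, s)
        alpha, _ = _kernels.forward_alphas(delta[0], delta[1], psi12, psi21, b)
        T = len(s)
        w = np.zeros((T, 2))
        w[0] = delta
        if T > 1:
            p12 = psi12[:-1]
            p21 = psi21[:-1]
            w[1:, 0] = alpha[:-1, 0] * (1.0 - p12) + alpha[:-1, 1] * p21
            w[1:, 1] = alpha[:-1, 0] * p12 + alpha[:-1, 1] * (1.0 - p21)

        F_step = np.zeros((T, 2))
        F_ang = np.zeros((T, 2))
        for k in (0, 1):
            m = np.exp(
                params.step.mean[k].linear_predictor(
                    s.trial_id, s.pump_on, s.co2_mgL, s.temp_C
                )
            )
            m = np.broadcast_to(np.asarray(m, dtype=float), s.step_m.shape)
            sd = params.step.sd(k + 1)
            p0 = params.step.zero_mass(k + 1)
            a = m * m / (sd * sd)
            sc = sd * sd / m
            gcdf = gammainc(a, np.maximum(s.step_m, 0.0) / sc)
            F_step[:, k] = p0 + (1.0 - p0) * np.where(s.step_m > 0, gcdf, 0.0)
            F_ang[:, k] = _vm_cdf_from_minus_pi(
                np.nan_to_num(s.angle_rad), float(params.angle.mu[k]),
                float(params.angle.kappa[k]),
            )

        u_step = np.clip((w * F_step).sum(axis=1), 1e-12, 1.0 - 1e-12)
        u_ang = np.clip((w * F_ang).sum(axis=1), 1e-12, 1.0 - 1e-12)
        z_step = ndtri(u_step)
        z_ang = np.where(np.isfinite(s.angle_rad), ndtri(u_ang), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "fish_id": s.fish_id,
                    "step_index": np.arange(T),
                    "step_resid": z_step,
                    "angle_resid": z_ang,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
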