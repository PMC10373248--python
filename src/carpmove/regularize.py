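"""Regularize irregular telemetry fixes onto a fixed time grid.

Acoustic positioning systems emit fixes at irregular intervals (here,
transmitter pulse gaps of roughly 1.3-5.9 s). Movement HMMs built on step
lengths and turning angles need positions on a regular grid. This module
fits a continuous-time correlated random walk (CTCRW) per fish -- an
integrated Ornstein-Uhlenbeck velocity process observed with Gaussian
positioning error -- by maximum likelihood through a Kalman filter over the
irregular fix times, then predicts positions on a 6-s grid with the
fixed-interval (RTS) smoother. Step lengths and turning angles with joined
per-step covariates are derived from the smoothed grid positions.

Model, per axis (shared parameters across x and y):

    dv(t) = -beta_vel * v(t) dt + sigma_vel dW(t)      (OU velocity)
    x(t)  = x(0) + integral_0^t v(s) ds                (integrated velocity)
    y_i   = x(t_i) + e_i,   e_i ~ N(0, tau_obs^2)      (positioning error)

beta_vel (1/s) is the velocity autocorrelation decay, sigma_vel the velocity
diffusion scale (m/s per sqrt(s)), and tau_obs (m) the positioning-error SD.
The discrete transition over a gap dt has exact Gaussian moments, so the
likelihood is exact for irregular sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _kernels
from .errors import FitError, ValidationError

__all__ = [
    "FixSeries",
    "CtcrwParams",
    "RegularTrack",
    "StepAngleSeries",
    "wrap_angle",
    "fit_ctcrw",
    "predict_regular",
    "simulate_ctcrw",
    "steps_and_angles",
]

DT_DEFAULT_S = 6.0  # regular grid spacing, seconds


def wrap_angle(a):
    """Wrap angle(s) to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = np.mod(a + np.pi, 2.0 * np.pi) - np.pi
    w = np.where(w == -np.pi, np.pi, w)
    return float(w) if w.ndim == 0 else w


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FixSeries:
    """Irregular timestamped 2-D positions for one fish in one trial."""

    fish_id: str
    t: np.ndarray  # seconds, strictly increasing
    x: np.ndarray  # meters
    y: np.ndarray  # meters
    trial_id: object = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError("FixSeries arrays must have equal length")
        if np.any(~np.isfinite(self.t)) or np.any(~np.isfinite(self.x)) or np.any(
            ~np.isfinite(self.y)
        ):
            raise ValidationError("FixSeries contains non-finite values")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValidationError(
                f"fix times must be strictly increasing (fish {self.fish_id})"
            )

    def __len__(self):
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fish_id": self.fish_id,
                "trial_id": self.trial_id,
                "t_s": self.t,
                "x_m": self.x,
                "y_m": self.y,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FixSeries":
        df = df.sort_values("t_s")
        return cls(
            fish_id=str(df["fish_id"].iloc[0]),
            t=df["t_s"].to_numpy(),
            x=df["x_m"].to_numpy(),
            y=df["y_m"].to_numpy(),
            trial_id=df["trial_id"].iloc[0] if "trial_id" in df else None,
        )


@dataclass
class CtcrwParams:
    """CTCRW parameters; see module docstring for the model."""

    beta_vel: float   # 1/s, > 0
    sigma_vel: float  # velocity diffusion scale, > 0
    tau_obs: float    # measurement-error SD, meters, >= 0
    loglik: float | None = None
    converged: bool | None = None

    def __post_init__(self):
        if not (self.beta_vel > 0):
            raise ValidationError("beta_vel must be > 0")
        if not (self.sigma_vel > 0):
            raise ValidationError("sigma_vel must be > 0")
        if self.tau_obs < 0:
            raise ValidationError("tau_obs must be >= 0")


@dataclass
class RegularTrack:
    """Positions on a regular time grid (smoother means) for one fish."""

    fish_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pred_se: np.ndarray | None = None  # sqrt(var_x + var_y), meters
    trial_id: object = None

    def __len__(self):
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fish_id": self.fish_id,
                "trial_id": self.trial_id,
                "t_s": self.t,
                "x_m": self.x,
                "y_m": self.y,
                "pred_se_m": self.pred_se
                if self.pred_se is not None
                else np.full(len(self.t), np.nan),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegularTrack":
        df = df.sort_values("t_s")
        return cls(
            fish_id=str(df["fish_id"].iloc[0]),
            t=df["t_s"].to_numpy(dtype=float),
            x=df["x_m"].to_numpy(dtype=float),
            y=df["y_m"].to_numpy(dtype=float),
            pred_se=df["pred_se_m"].to_numpy(dtype=float)
            if "pred_se_m" in df
            else None,
            trial_id=df["trial_id"].iloc[0] if "trial_id" in df else None,
        )


@dataclass
class StepAngleSeries:
    """Step lengths, turning angles, and per-step covariates for one fish.

    ``angle_rad[k]`` is the signed change in movement bearing from step k-1
    to step k, wrapped to (-pi, pi]; it is NaN for the first step of a track
    and wherever an adjacent step has zero length (bearing undefined).
    Covariates are taken at each step's start time.
    """

    fish_id: str
    trial_id: object
    t_s: np.ndarray        # step start times
    step_m: np.ndarray     # >= 0, meters per grid interval
    angle_rad: np.ndarray  # (-pi, pi] or NaN
    pump_on: np.ndarray    # {0, 1}
    co2_mgL: np.ndarray
    temp_C: np.ndarray

    def __post_init__(self):
        if np.any(self.step_m < 0):
            raise ValidationError("step lengths must be nonnegative")

    def __len__(self):
        return len(self.step_m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fish_id": self.fish_id,
                "trial_id": self.trial_id,
                "step_index": np.arange(len(self.step_m)),
                "t_s": self.t_s,
                "step_m": self.step_m,
                "angle_rad": self.angle_rad,
                "pump_on": self.pump_on,
                "co2_mgL": self.co2_mgL,
                "temp_C": self.temp_C,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StepAngleSeries":
        df = df.sort_values("step_index")
        return cls(
            fish_id=str(df["fish_id"].iloc[0]),
            trial_id=df["trial_id"].iloc[0],
            t_s=df["t_s"].to_numpy(dtype=float),
            step_m=df["step_m"].to_numpy(dtype=float),
            angle_rad=df["angle_rad"].to_numpy(dtype=float),
            pump_on=df["pump_on"].to_numpy(dtype=int),
            co2_mgL=df["co2_mgL"].to_numpy(dtype=float),
            temp_C=df["temp_C"].to_numpy(dtype=float),
        )


# ---------------------------------------------------------------------------
# exact discrete-time CTCRW moments
# ---------------------------------------------------------------------------

def _transition_moments(beta: float, sigma: float, dts: np.ndarray):
    """Exact transition matrices F and noise covariances Q over gaps ``dts``.

    State is (position, velocity) per axis. Small beta*dt uses a series
    expansion of the position variance to avoid catastrophic cancellation.
    """
    dts = np.asarray(dts, dtype=float)
    u = beta * dts
    em1 = -np.expm1(-u)       # 1 - exp(-u), stable
    em2 = -np.expm1(-2.0 * u)  # 1 - exp(-2u)
    q = sigma * sigma

    n = len(dts)
    F = np.zeros((n, 2, 2))
    F[:, 0, 0] = 1.0
    F[:, 0, 1] = em1 / beta
    F[:, 1, 1] = np.exp(-u)

    # g(u) = u - 2(1-e^-u) + (1-e^-2u)/2 = u^3/3 - u^4/4 + 7u^5/60 - ...
    g = np.where(
        u < 1e-3,
        u**3 / 3.0 - u**4 / 4.0 + 7.0 * u**5 / 60.0,
        u - 2.0 * em1 + 0.5 * em2,
    )
    Q = np.zeros((n, 2, 2))
    Q[:, 0, 0] = q / beta**3 * g
    Q[:, 0, 1] = Q[:, 1, 0] = q / (2.0 * beta**2) * em1**2
    Q[:, 1, 1] = q / (2.0 * beta) * em2
    return F, Q


def _kalman_axis(times, obs_idx, y, beta, sigma, tau, smooth=False):
    """Kalman filter (and optional RTS smoother) for one axis.

    ``times`` are the augmented, strictly increasing timestamps;
    ``obs_idx`` is a boolean mask of which times carry an observation in
    ``y`` (len(y) == obs_idx.sum()). Returns the log-likelihood, and when
    ``smooth`` the smoothed means and position variances at all times.
    """
    n = len(times)
    F, Q = _transition_moments(beta, sigma, np.diff(times))
    R = tau * tau

    a = np.array([y[0], 0.0])
    # diffuse-ish position prior anchored at the first observation;
    # velocity starts at its stationary distribution
    P = np.diag([1e6, sigma * sigma / (2.0 * beta)])

    a_pred = np.zeros((n, 2))
    P_pred = np.zeros((n, 2, 2))
    a_filt = np.zeros((n, 2))
    P_filt = np.zeros((n, 2, 2))

    ll = 0.0
    k_obs = 0
    for i in range(n):
        if i > 0:
            Fi = F[i - 1]
            a = Fi @ a
            P = Fi @ P @ Fi.T + Q[i - 1]
        a_pred[i] = a
        P_pred[i] = P
        if obs_idx[i]:
            v = y[k_obs] - a[0]
            S = P[0, 0] + R
            ll += -0.5 * (np.log(2.0 * np.pi * S) + v * v / S)
            K = P[:, 0] / S
            a = a + K * v
            # Joseph form keeps P positive semidefinite when tau ~ 0
            IKH = np.eye(2)
            IKH[:, 0] -= K
            P = IKH @ P @ IKH.T + np.outer(K, K) * R
            k_obs += 1
        a_filt[i] = a
        P_filt[i] = P

    if not smooth:
        return ll, None, None

    a_s = a_filt.copy()
    P_s = P_filt.copy()
    for i in range(n - 2, -1, -1):
        Fi = F[i]
        Pp = P_pred[i + 1]
        # guard against singular predicted covariance on zero-length gaps
        C = P_filt[i] @ Fi.T @ np.linalg.pinv(Pp)
        a_s[i] = a_filt[i] + C @ (a_s[i + 1] - a_pred[i + 1])
        P_s[i] = P_filt[i] + C @ (P_s[i + 1] - P_pred[i + 1]) @ C.T
    return ll, a_s, P_s


def _neg_loglik(log_params, fixes: FixSeries):
    beta, sigma, tau = np.exp(log_params)
    F, Q = _transition_moments(beta, sigma, np.diff(fixes.t))
    f01, f11 = F[:, 0, 1], F[:, 1, 1]
    q00, q01, q11 = Q[:, 0, 0], Q[:, 0, 1], Q[:, 1, 1]
    R = tau * tau
    p11_init = sigma * sigma / (2.0 * beta)
    llx = _kernels.ctcrw_filter_ll(fixes.x, f01, f11, q00, q01, q11, R, 1e6, p11_init)
    lly = _kernels.ctcrw_filter_ll(fixes.y, f01, f11, q00, q01, q11, R, 1e6, p11_init)
    ll = llx + lly
    if not np.isfinite(ll):
        return 1e12
    return -ll


_LOG_BOUNDS = [
    (np.log(1e-5), np.log(1e3)),   # beta_vel
    (np.log(1e-6), np.log(1e3)),   # sigma_vel
    (np.log(1e-6), np.log(1e2)),   # tau_obs
]


def _default_init(fixes: FixSeries) -> CtcrwParams:
    dt = np.diff(fixes.t)
    vx = np.diff(fixes.x) / dt
    vy = np.diff(fixes.y) / dt
    v_sd = max(float(np.std(np.concatenate([vx, vy]))), 1e-3)
    dt_med = max(float(np.median(dt)), 1e-3)
    beta0 = 1.0 / (5.0 * dt_med)
    return CtcrwParams(
        beta_vel=beta0, sigma_vel=v_sd * np.sqrt(2.0 * beta0), tau_obs=0.5
    )


def fit_ctcrw(
    fixes: FixSeries,
    init: CtcrwParams | None = None,
    n_restarts: int = 3,
    seed: int = 0,
) -> CtcrwParams:
    """Fit CTCRW parameters to an irregular fix series by maximum likelihood.

    Optimization is quasi-Newton (L-BFGS-B) on log-parameters, with
    ``n_restarts`` seeded perturbed restarts. Raises :class:`FitError`
    (carrying the best parameters found) if no restart converges.
    """
    if len(fixes) < 4:
        raise ValidationError(
            f"need at least 4 fixes to fit CTCRW, got {len(fixes)}"
        )
    if init is None:
        init = _default_init(fixes)
    theta0 = np.log([init.beta_vel, init.sigma_vel, init.tau_obs or 0.5])
    theta0 = np.clip(
        theta0, [b[0] for b in _LOG_BOUNDS], [b[1] for b in _LOG_BOUNDS]
    )

    rng = np.random.default_rng(seed)
    best = None
    any_success = False
    for r in range(max(1, n_restarts)):
        start = theta0 if r == 0 else theta0 + rng.normal(0.0, 0.7, size=3)
        start = np.clip(
            start, [b[0] for b in _LOG_BOUNDS], [b[1] for b in _LOG_BOUNDS]
        )
        res = minimize(
            _neg_loglik,
            start,
            args=(fixes,),
            method="L-BFGS-B",
            bounds=_LOG_BOUNDS,
            options={"maxiter": 300},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    beta, sigma, tau = np.exp(best.x)
    params = CtcrwParams(
        beta_vel=float(beta),
        sigma_vel=float(sigma),
        tau_obs=float(tau),
        loglik=float(-best.fun),
        converged=any_success,
    )
    if not any_success:
        raise FitError(
            f"CTCRW fit did not converge for fish {fixes.fish_id}",
            best_params=params,
        )
    return params


def predict_regular(
    fixes: FixSeries, params: CtcrwParams, dt_s: float = DT_DEFAULT_S
) -> RegularTrack:
    """Smoothed positions on the grid t0 + k*dt_s covering the fix span.

    The grid is anchored at the first fix time and never extrapolates past
    the last fix. ``pred_se`` is sqrt(var_x + var_y) from the smoother.
    """
    if dt_s <= 0:
        raise ValidationError("dt_s must be positive")
    if len(fixes) < 2:
        raise ValidationError("need at least 2 fixes to predict a track")

    t0, t_end = fixes.t[0], fixes.t[-1]
    n_grid = int(np.floor((t_end - t0) / dt_s + 1e-9)) + 1
    grid = t0 + dt_s * np.arange(n_grid)

    # merge grid and fix times; an augmented time is "observed" if a fix
    # falls on it (within 1e-9 s)
    all_t = np.unique(np.concatenate([grid, fixes.t]))
    obs_mask = np.isin(np.round(all_t, 9), np.round(fixes.t, 9))
    grid_pos = np.searchsorted(all_t, grid)

    beta, sigma, tau = params.beta_vel, params.sigma_vel, max(params.tau_obs, 1e-8)
    _, ax_s, Px_s = _kalman_axis(all_t, obs_mask, fixes.x, beta, sigma, tau, smooth=True)
    _, ay_s, Py_s = _kalman_axis(all_t, obs_mask, fixes.y, beta, sigma, tau, smooth=True)

    var = np.clip(Px_s[grid_pos, 0, 0], 0, None) + np.clip(Py_s[grid_pos, 0, 0], 0, None)
    return RegularTrack(
        fish_id=fixes.fish_id,
        t=grid,
        x=ax_s[grid_pos, 0],
        y=ay_s[grid_pos, 0],
        pred_se=np.sqrt(var),
        trial_id=fixes.trial_id,
    )


def simulate_ctcrw(
    params: CtcrwParams,
    n_fixes: int,
    seed: int,
    gap_range_s: tuple = (1.301, 5.862),
    start_xy: tuple = (0.0, 0.0),
    fish_id: str = "sim",
) -> FixSeries:
    """Simulate an irregular fix series from the CTCRW model itself.

    Gaps are uniform over ``gap_range_s`` (the transmitter pulse-rate
    range); each axis follows the exact integrated-OU transition moments
    with velocity started at its stationary distribution, plus Gaussian
    positioning error. Used for parameter-recovery studies.
    """
    if n_fixes < 2:
        raise ValidationError("n_fixes must be >= 2")
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(*gap_range_s, size=n_fixes - 1)
    t = np.concatenate([[0.0], np.cumsum(gaps)])
    beta, sigma, tau = params.beta_vel, params.sigma_vel, params.tau_obs
    F, Q = _transition_moments(beta, sigma, gaps)
    chol = np.linalg.cholesky(Q + 1e-14 * np.eye(2))
    pos = np.zeros((n_fixes, 2))
    v_sd = sigma / np.sqrt(2.0 * beta)
    for ax, x0 in enumerate(start_xy):
        s = np.array([x0, rng.normal(0.0, v_sd)])
        pos[0, ax] = s[0]
        for i in range(n_fixes - 1):
            s = F[i] @ s + chol[i] @ rng.normal(size=2)
            pos[i + 1, ax] = s[0]
    noisy = pos + rng.normal(0.0, tau, size=pos.shape)
    return FixSeries(fish_id=fish_id, t=t, x=noisy[:, 0], y=noisy[:, 1])


# ---------------------------------------------------------------------------
# step lengths, turning angles, covariate join
# ---------------------------------------------------------------------------

def steps_and_angles(
    track: RegularTrack, covariates: pd.DataFrame
) -> StepAngleSeries:
    """Derive step lengths, turning angles, and per-step covariates.

    ``covariates`` must have columns t_s, pump_on, co2_mgL, temp_C covering
    the track's time span; values are joined by nearest time at each step's
    start. Left turns are positive (counter-clockwise bearing convention).
    """
    if len(track) < 2:
        raise ValidationError("track must have at least 2 positions")
    for col in ("t_s", "pump_on", "co2_mgL", "temp_C"):
        if col not in covariates.columns:
            raise ValidationError(f"covariate table missing column {col!r}")

    dx = np.diff(track.x)
    dy = np.diff(track.y)
    step = np.hypot(dx, dy)
    bearing = np.arctan2(dy, dx)

    n_steps = len(step)
    angle = np.full(n_steps, np.nan)
    if n_steps >= 2:
        ang = wrap_angle(bearing[1:] - bearing[:-1])
        # undefined when either adjacent step has zero length
        bad = (step[1:] == 0.0) | (step[:-1] == 0.0)
        ang = np.where(bad, np.nan, ang)
        angle[1:] = ang

    cov = covariates.sort_values("t_s").reset_index(drop=True)
    t_start = track.t[:-1]
    dt_track = float(track.t[1] - track.t[0]) if len(track) > 1 else DT_DEFAULT_S
    dt_cov = float(np.max(np.diff(cov["t_s"]))) if len(cov) > 1 else dt_track
    lo = cov["t_s"].iloc[0] - dt_cov
    hi = cov["t_s"].iloc[-1] + dt_cov
    if t_start[0] < lo or t_start[-1] > hi:
        raise ValidationError(
            "covariate table does not cover the track's time span "
            f"(track [{t_start[0]:.1f}, {t_start[-1]:.1f}] s vs covariates "
            f"[{cov['t_s'].iloc[0]:.1f}, {cov['t_s'].iloc[-1]:.1f}] s)"
        )
    idx = np.clip(
        np.searchsorted(cov["t_s"].to_numpy(), t_start), 0, len(cov) - 1
    )
    # nearest, not just right neighbor
    left = np.clip(idx - 1, 0, len(cov) - 1)
    use_left = np.abs(cov["t_s"].to_numpy()[left] - t_start) < np.abs(
        cov["t_s"].to_numpy()[idx] - t_start
    )
    idx = np.where(use_left, left, idx)

    return StepAngleSeries(
        fish_id=track.fish_id,
        trial_id=track.trial_id,
        t_s=t_start,
        step_m=step,
        angle_rad=angle,
        pump_on=cov["pump_on"].to_numpy(dtype=int)[idx],
        co2_mgL=cov["co2_mgL"].to_numpy(dtype=float)[idx],
        temp_C=cov["temp_C"].to_numpy(dtype=float)[idx],
    )
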