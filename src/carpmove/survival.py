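"""Kaplan-Meier time-to-exit analysis with right censoring.

"Survival" here means still inside the lock chamber: the event is a fish
crossing the open downstream gate line, and fish still inside at the trial
horizon (90 min by default) are right-censored. The product-limit curve and
its median are computed through lifelines; the Greenwood standard error is
derived from the event table. Ties between events and censorings at the
same time follow the standard convention (events first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import ValidationError
from .regularize import RegularTrack
from .simulate import LockArena

__all__ = [
    "ExitRecord",
    "KmEstimate",
    "detect_exit",
    "km_estimate",
    "median_exit",
    "remaining_proportion",
]

HORIZON_MIN_DEFAULT = 90.0


@dataclass
class ExitRecord:
    """Time-to-exit of one fish, in minutes from gate opening."""

    fish_id: str
    trial_id: object
    treatment_label: str | None
    time_min: float
    event: int  # 1 = exited, 0 = censored at horizon

    def __post_init__(self):
        if self.time_min <= 0:
            raise ValidationError("exit time must be positive")
        if self.event not in (0, 1):
            raise ValidationError("event must be 0 or 1")


@dataclass
class KmEstimate:
    """Product-limit survival estimate with Greenwood standard errors."""

    event_times: np.ndarray   # minutes, distinct event times
    survival: np.ndarray      # S(t) at each event time
    n_risk: np.ndarray
    n_event: np.ndarray
    greenwood_se: np.ndarray
    median_exit_min: float    # first t with S(t) <= 0.5 (inf if never)
    n_total: int

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.event_times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
                "greenwood_se": self.greenwood_se,
            }
        )


def detect_exit(
    track: RegularTrack,
    arena: LockArena,
    horizon_min: float = HORIZON_MIN_DEFAULT,
    end_of_track_is_exit: bool = True,
    grace_s: float = 60.0,
) -> ExitRecord:
    """Derive an exit record from a regularized track.

    The exit time is the first grid time whose position is beyond the gate
    line (x < gate_x, downstream), linearly interpolated between the
    bracketing grid positions. Tracks that never cross are censored at the
    horizon -- unless ``end_of_track_is_exit`` and the track ends more than
    ``grace_s`` before the horizon, in which case the fish left receiver
    coverage through the gate and the track end is the exit time.
    """
    if len(track) < 1:
        raise ValidationError("empty track")
    if track.x[0] < arena.gate_x:
        raise ValidationError(
            f"track for fish {track.fish_id} starts beyond the gate line"
        )
    t0 = track.t[0]
    # exact hits on the gate line count as exits at that grid time
    hit = np.flatnonzero(track.x <= arena.gate_x)
    if len(hit):
        j = int(hit[0])
        if track.x[j] == arena.gate_x or j == 0:
            t_exit = track.t[j]
        else:
            xa, xb = track.x[j - 1], track.x[j]
            frac = (xa - arena.gate_x) / (xa - xb)
            t_exit = track.t[j - 1] + frac * (track.t[j] - track.t[j - 1])
        return ExitRecord(
            fish_id=track.fish_id,
            trial_id=track.trial_id,
            treatment_label=None,
            time_min=float(max((t_exit - t0) / 60.0, 1e-9)),
            event=1,
        )
    span_s = track.t[-1] - t0
    if end_of_track_is_exit and span_s < horizon_min * 60.0 - grace_s:
        return ExitRecord(
            fish_id=track.fish_id,
            trial_id=track.trial_id,
            treatment_label=None,
            time_min=float(max(span_s, 1e-9) / 60.0),
            event=1,
        )
    return ExitRecord(
        fish_id=track.fish_id,
        trial_id=track.trial_id,
        treatment_label=None,
        time_min=float(horizon_min),
        event=0,
    )


def km_estimate(records) -> KmEstimate:
    """Product-limit survival estimate from exit records."""
    records = list(records)
    if not records:
        raise ValidationError("records must be nonempty")
    times = np.array([r.time_min for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if np.any(times <= 0):
        raise ValidationError("exit times must be positive")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    tab = tab[tab["observed"] > 0]
    event_times = tab.index.to_numpy(dtype=float)
    n_risk = tab["at_risk"].to_numpy(dtype=float)
    n_event = tab["observed"].to_numpy(dtype=float)
    surv = np.array([float(kmf.predict(t)) for t in event_times])

    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(
            n_risk > n_event, n_event / (n_risk * (n_risk - n_event)), 0.0
        )
    se = surv * np.sqrt(np.cumsum(inc))

    med = kmf.median_survival_time_
    return KmEstimate(
        event_times=event_times,
        survival=surv,
        n_risk=n_risk.astype(int),
        n_event=n_event.astype(int),
        greenwood_se=se,
        median_exit_min=float(med),
        n_total=len(records),
    )


def median_exit(records, horizon_min: float = HORIZON_MIN_DEFAULT):
    """Median time-to-exit under the horizon-assignment convention.

    Returns (sample_median_min, km_median_min): the sample median with
    censored times set to the horizon, plus the Kaplan-Meier median (first
    time the survival curve drops to 0.5 or below) as a secondary output.
    """
    records = list(records)
    if not records:
        raise ValidationError("records must be nonempty")
    t = np.array(
        [r.time_min if r.event else horizon_min for r in records], dtype=float
    )
    return float(np.median(t)), km_estimate(records).median_exit_min


def remaining_proportion(n_remaining: int, n_start: int):
    """Percent of fish remaining at trial end, with binomial SE (percent)."""
    if n_start < 1:
        raise ValidationError("n_start must be >= 1")
    if not (0 <= n_remaining <= n_start):
        raise ValidationError("need 0 <= n_remaining <= n_start")
    p = n_remaining / n_start
    return 100.0 * p, 100.0 * float(np.sqrt(p * (1.0 - p) / n_start))
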