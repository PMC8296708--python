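"""Functional-readout metrics: normalized grip strength, treadmill
distance under the exhaustion ramp, and drinking-water dose estimation.

Grip strength follows the 5-trials-per-session protocol: the maximal force
of a session normalized to body weight is FNmax, and the highest FNmax
across all time points is the per-mouse summary.  The treadmill exhaustion
protocol runs flat at 5 m/min for 5 min, then the belt speed increases by
1 m/min every minute until exhaustion; distance is the integral of that
speed profile.  For drinking-water dosing the daily dose is estimated from
drug concentration, a nominal water intake (4 mL/mouse/day) and body
weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TRIALS_PER_SESSION",
    "GripSession",
    "TreadmillSession",
    "ProtocolViolationError",
    "InvalidTimeError",
    "fnmax",
    "fnmax_trajectory",
    "treadmill_distance",
    "estimate_water_dose",
    "grip_group_summary",
    "treadmill_group_summary",
]

#: Grip protocol trial count per mouse per session.
TRIALS_PER_SESSION = 5

RAMP_FLAT_SPEED = 5.0  # m/min during the flat phase
RAMP_FLAT_MIN = 5.0  # duration of the flat phase, min
RAMP_INCREMENT = 1.0  # m/min added at each whole minute after the flat phase


class ProtocolViolationError(ValueError):
    """Session breaks the protocol (e.g. wrong trial count)."""


class InvalidTimeError(ValueError):
    """Negative exhaustion time."""


@dataclass(frozen=True)
class GripSession:
    """One grip-test session: 5 trial forces plus the body weight."""

    mouse_id: str
    week: int
    forces: tuple[float, ...]
    bw_g: float

    def __post_init__(self) -> None:
        forces = tuple(float(f) for f in self.forces)
        if len(forces) != TRIALS_PER_SESSION:
            raise ProtocolViolationError(
                f"protocol requires {TRIALS_PER_SESSION} trials, got {len(forces)}"
            )
        if any(f <= 0 for f in forces) or self.bw_g <= 0:
            raise ValueError("forces and body weight must be positive")
        object.__setattr__(self, "forces", forces)


@dataclass(frozen=True)
class TreadmillSession:
    """One treadmill run: exhaustion time, accumulated shocks, cap flag."""

    mouse_id: str
    day: int
    exhaustion_time_min: float
    shocks: int = 0
    capped: bool = False

    def __post_init__(self) -> None:
        if self.exhaustion_time_min < 0:
            raise InvalidTimeError("exhaustion time must be >= 0")
        if self.shocks < 0:
            raise ValueError("shock count must be >= 0")


def fnmax(session: GripSession) -> float:
    """Maximal normalized strength: best of 5 trials per gram body weight."""
    return max(session.forces) / session.bw_g


def fnmax_trajectory(sessions: list[GripSession]) -> pd.DataFrame:
    """Per-week FNmax for one mouse, with the across-week peak flagged.

    Returns a frame (week, fnmax, is_peak) sorted by week; the highest
    FNmax over all time points (earliest week on ties) is the per-mouse
    value used for downstream analysis.
    """
    if not sessions:
        raise ValueError("no sessions")
    mice = {s.mouse_id for s in sessions}
    if len(mice) != 1:
        raise ValueError("trajectory expects sessions from a single mouse")
    rows = sorted(((s.week, fnmax(s)) for s in sessions), key=lambda r: r[0])
    df = pd.DataFrame(rows, columns=["week", "fnmax"])
    peak_idx = int(df["fnmax"].idxmax())
    df["is_peak"] = False
    df.loc[peak_idx, "is_peak"] = True
    return df


def treadmill_distance(exhaustion_time_min: float) -> float:
    """Distance run (m) after ``t`` minutes of the exhaustion ramp.

    Flat phase: 5 m/min for the first 5 min.  During minute n > 5 the speed
    is 5 + (n - 5) m/min; a partial final minute is prorated linearly, so
    the distance is continuous, piecewise linear and strictly increasing.
    """
    t = float(exhaustion_time_min)
    if t < 0:
        raise InvalidTimeError("time must be >= 0")
    if t <= RAMP_FLAT_MIN:
        return RAMP_FLAT_SPEED * t
    ramp_t = t - RAMP_FLAT_MIN
    whole = math.floor(ramp_t)
    # completed ramp minutes run at 6, 7, ..., 5 + whole m/min
    ramp_dist = sum(
        RAMP_FLAT_SPEED + i * RAMP_INCREMENT for i in range(1, whole + 1)
    )
    partial = (ramp_t - whole) * (RAMP_FLAT_SPEED + (whole + 1) * RAMP_INCREMENT)
    return RAMP_FLAT_SPEED * RAMP_FLAT_MIN + ramp_dist + partial


def estimate_water_dose(
    conc_mg_per_ml: float, water_ml_per_mouse_day: float, bw_g: float
) -> float:
    """Daily dose (mg/kg/day) from drinking-water drug concentration.

    dose = concentration x daily water intake / body weight in kg; the
    nominal intake used in study design is 4 mL/mouse/day.
    """
    if conc_mg_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    if water_ml_per_mouse_day <= 0 or bw_g <= 0:
        raise ValueError("water intake and body weight must be positive")
    return conc_mg_per_ml * water_ml_per_mouse_day / (bw_g / 1000.0)


def grip_group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Group x week FNmax summary (mean, s.e., n) from a trial-level table.

    Expects columns (mouse_id, group, week, trial, force, bw_g) as written
    by the synthetic generator; trials are collapsed to per-session FNmax
    first.
    """
    per_session = (
        table.groupby(["group", "mouse_id", "week"])
        .apply(
            lambda g: g["force"].max() / g["bw_g"].iloc[0],
            include_groups=False,
        )
        .rename("fnmax")
        .reset_index()
    )
    return _summarise(per_session, ["group", "week"], "fnmax")


def treadmill_group_summary(
    table: pd.DataFrame, include_capped: bool = True
) -> pd.DataFrame:
    """Group x day distance summary from a treadmill session table.

    Expects columns (mouse_id, group, day, time_min, shocks, capped).
    Cap-truncated sessions are censored observations; by default they are
    included (their recorded time is a lower bound), set
    ``include_capped=False`` to drop them.  A ``n_capped`` column reports
    how many censored sessions each cell contains.
    """
    df = table.copy()
    df["distance_m"] = df["time_min"].map(treadmill_distance)
    if not include_capped:
        df = df[~df["capped"]]
    out = _summarise(df, ["group", "day"], "distance_m")
    n_capped = (
        table.groupby(["group", "day"])["capped"].sum().rename("n_capped")
    )
    return out.merge(n_capped.reset_index(), on=["group", "day"], how="left")


def _summarise(df: pd.DataFrame, by: list[str], value: str) -> pd.DataFrame:
    g = df.groupby(by)[value]
    out = g.agg(mean="mean", n="count")
    sd = g.std(ddof=1).fillna(0.0)
    out["se"] = (sd / np.sqrt(out["n"])).fillna(0.0)
    return out.reset_index()[by + ["mean", "se", "n"]]
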