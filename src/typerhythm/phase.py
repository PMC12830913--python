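"""Daily activity phase and time-zone transition analysis.

Each day's score row is read in polar coordinates: hour of day (UTC) maps to
an angle and the (non-negative) score to a vector length. The weighted
circular mean of those vectors points at the time of peak typing activity;
its angle is the day's phase. Phases are computed in UTC so that travel
across time zones shows up as genuine phase shifts instead of being hidden
by local clock changes: moving west makes a person active later relative to
UTC (phase increase), moving east earlier (phase decrease).

Transitions are located in the per-day UTC-offset series, required to
persist, centred on the circular mean phase of the days immediately before
the change, and the east/west groups compared per offset day with Welch's
unequal-variance t-test.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sessions import ValidationError

logger = logging.getLogger(__name__)

_EPS_RESULTANT = 1e-12


def _hour_angles(n_hours: int = 24) -> np.ndarray:
    # Bin-centre convention: the aggregate for hour h represents the whole
    # hour, so its angle sits at h + 0.5.
    return 2 * np.pi * (np.arange(n_hours) + 0.5) / n_hours


def transform_weights(scores: np.ndarray, how: str = "clip") -> np.ndarray:
    """Map scores to non-negative circular weights (a vector length cannot
    be negative).

    ``clip`` zeroes negative scores; ``shift-min`` subtracts each day's
    minimum; ``softplus`` applies log(1 + exp(s)).
    """
    s = np.asarray(scores, dtype=float)
    if how == "clip":
        return np.clip(s, 0.0, None)
    if how == "shift-min":
        return s - s.min(axis=-1, keepdims=True)
    if how == "softplus":
        return np.logaddexp(0.0, s)
    raise ValidationError(f"unknown weight transform '{how}'")


def daily_phase(
    scores: np.ndarray,
    days: list[dt.date] | None = None,
    weight_transform: str = "clip",
) -> pd.DataFrame:
    """Weighted circular mean phase for every day (row) of a score matrix.

    Returns columns ``date``, ``phase_angle`` (radians in [0, 2pi)),
    ``phase_hours`` (= angle * 24 / 2pi), ``resultant_length`` (norm of the
    weight-normalised mean vector; near 0 means no coherent phase) and
    ``defined`` (False when all weights vanish or the vectors cancel).
    """
    mat = np.atleast_2d(np.asarray(scores, dtype=float))
    if not np.all(np.isfinite(mat)):
        raise ValidationError("scores must be finite")
    n_days, n_hours = mat.shape
    if days is None:
        days = list(range(n_days))

    theta = _hour_angles(n_hours)
    w = transform_weights(mat, weight_transform)
    C = w @ np.cos(theta)
    S = w @ np.sin(theta)
    wsum = w.sum(axis=1)
    resultant = np.sqrt(C**2 + S**2)

    defined = (wsum > 0) & (resultant > _EPS_RESULTANT)
    angle = np.where(defined, np.mod(np.arctan2(S, C), 2 * np.pi), np.nan)
    # np.mod can return exactly 2*pi for a tiny negative input; fold it back
    angle = np.where(angle >= 2 * np.pi, 0.0, angle)
    res_len = np.divide(
        resultant, wsum, out=np.zeros(n_days), where=wsum > 0
    )
    res_len = np.where(defined, res_len, 0.0)

    return pd.DataFrame({
        "date": [d.isoformat() if hasattr(d, "isoformat") else d for d in days],
        "phase_angle": angle,
        "phase_hours": angle * 24 / (2 * np.pi),
        "resultant_length": res_len,
        "defined": defined,
    })


def circular_mean_hours(hours: np.ndarray) -> float:
    """Unweighted circular mean of clock hours, on [0, 24)."""
    ang = np.asarray(hours, dtype=float) * 2 * np.pi / 24
    mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((np.mod(mean, 2 * np.pi) * 24 / (2 * np.pi)) % 24.0)


def circular_diff_hours(a: float, b: float) -> float:
    """Signed shortest difference a - b on the 24 h circle, in (-12, +12]."""
    d = np.mod(a - b, 24.0)
    return float(d if d <= 12.0 else d - 24.0)


@dataclass(frozen=True)
class Transition:
    """A persistent change of UTC offset.

    ``date`` is the first day at the new offset; ``direction`` is 'east' for
    an offset increase and 'west' for a decrease; ``persisted_days`` counts
    consecutive days (including ``date``) the new offset was held.
    """

    date: dt.date
    from_offset: int
    to_offset: int
    persisted_days: int

    def __post_init__(self) -> None:
        if self.to_offset == self.from_offset:
            raise ValidationError("transition requires an offset change")
        if self.persisted_days < 1:
            raise ValidationError("persisted_days must be >= 1")

    @property
    def direction(self) -> str:
        return "east" if self.to_offset > self.from_offset else "west"

    @property
    def magnitude_hours(self) -> float:
        return abs(self.to_offset - self.from_offset) / 60.0


def detect_transitions(
    daily_offsets: pd.Series | pd.DataFrame,
    min_persist: int = 7,
    min_magnitude_hours: float = 0.0,
) -> list[Transition]:
    """Find UTC-offset change-points that persist.

    Parameters
    ----------
    daily_offsets : Series (date-indexed) or DataFrame with columns
        ``date`` and ``utc_offset_min`` — one signed offset (minutes) per
        consecutive day.
    min_persist : int
        The new offset must be held for at least this many consecutive days
        (counting the transition day); a change that reverts sooner — or
        whose persistence window contains a further change — is discarded.
    min_magnitude_hours : float
        Keep only transitions of at least this magnitude (e.g. 2.0 to
        restrict to >= 2 h zone differences).
    """
    if isinstance(daily_offsets, pd.DataFrame):
        dates = [
            d if isinstance(d, dt.date) else dt.date.fromisoformat(str(d))
            for d in daily_offsets["date"]
        ]
        offsets = daily_offsets["utc_offset_min"].to_numpy()
    else:
        dates = [
            d if isinstance(d, dt.date) else dt.date.fromisoformat(str(d))
            for d in daily_offsets.index
        ]
        offsets = daily_offsets.to_numpy()
    offsets = np.asarray(offsets, dtype=int)
    if any(
        (b - a) != dt.timedelta(days=1) for a, b in zip(dates, dates[1:])
    ):
        raise ValidationError("daily offsets must cover consecutive days")

    out: list[Transition] = []
    n = len(offsets)
    for i in range(1, n):
        if offsets[i] == offsets[i - 1]:
            continue
        run = 1
        while i + run < n and offsets[i + run] == offsets[i]:
            run += 1
        if run < min_persist:
            continue
        t = Transition(
            date=dates[i],
            from_offset=int(offsets[i - 1]),
            to_offset=int(offsets[i]),
            persisted_days=run,
        )
        if t.magnitude_hours >= min_magnitude_hours:
            out.append(t)
    return out


def centre_transition_phases(
    phases: pd.DataFrame,
    transition: Transition,
    pre_days: int = 3,
    post_days: int = 7,
) -> pd.DataFrame | None:
    """Centre the phases around a transition on its pre-transition baseline.

    The baseline is the unweighted circular mean of the defined daily phase
    angles over the ``pre_days`` days before the transition. Each offset day
    in [-pre_days, +post_days] reports the signed circular difference
    (phase - baseline) mapped into (-12, +12] hours; wrap-around through
    midnight is therefore handled (a 23 h baseline and a 1 h phase give
    +2 h, not -22 h). Returns None — with a logged reason — when no defined
    phase exists in the pre-transition window.
    """
    dates = [dt.date.fromisoformat(str(d)) for d in phases["date"]]
    by_date = {
        d: (row.phase_hours, bool(row.defined))
        for d, row in zip(dates, phases.itertuples(index=False))
    }

    pre = []
    for k in range(-pre_days, 0):
        entry = by_date.get(transition.date + dt.timedelta(days=k))
        if entry is not None and entry[1]:
            pre.append(entry[0])
    if not pre:
        logger.info(
            "transition at %s excluded: no defined phase in the %d-day "
            "pre-transition window", transition.date, pre_days,
        )
        return None
    baseline = circular_mean_hours(np.asarray(pre))

    rows = []
    for k in range(-pre_days, post_days + 1):
        entry = by_date.get(transition.date + dt.timedelta(days=k))
        if entry is None or not entry[1]:
            continue
        rows.append({
            "transition_date": transition.date.isoformat(),
            "direction": transition.direction,
            "magnitude_hours": transition.magnitude_hours,
            "offset_day": k,
            "centred_hours": circular_diff_hours(entry[0], baseline),
        })
    return pd.DataFrame(rows)


def centred_transition_table(
    phases: pd.DataFrame,
    transitions: list[Transition],
    pre_days: int = 3,
    post_days: int = 7,
) -> pd.DataFrame:
    """Stack per-transition centred phases into one long table."""
    parts = [
        centre_transition_phases(phases, t, pre_days, post_days)
        for t in transitions
    ]
    parts = [p for p in parts if p is not None and len(p)]
    if not parts:
        return pd.DataFrame(columns=[
            "transition_date", "direction", "magnitude_hours",
            "offset_day", "centred_hours",
        ])
    return pd.concat(parts, ignore_index=True)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test of a vs b (two-sided).

    Returns (t, Welch–Satterthwaite df, p)."""
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_directions(centred: pd.DataFrame, day: int) -> dict:
    """Welch's t-test of east vs west centred phases at one offset day.

    The statistic is computed as east minus west. With fewer than two
    observations in either group the result is flagged not computable.
    """
    sub = centred[centred["offset_day"] == day]
    east = sub.loc[sub["direction"] == "east", "centred_hours"].to_numpy()
    west = sub.loc[sub["direction"] == "west", "centred_hours"].to_numpy()
    out = {
        "offset_day": day,
        "n_east": int(east.size),
        "n_west": int(west.size),
        "computable": bool(east.size >= 2 and west.size >= 2),
    }
    if not out["computable"]:
        out.update(t=np.nan, df=np.nan, p=np.nan, stars="")
        return out
    t, df, p = welch_t(east, west)
    out.update(t=t, df=df, p=p, stars=significance_stars(p))
    return out


def direction_test_table(
    centred: pd.DataFrame,
    days: list[int] | None = None,
) -> pd.DataFrame:
    """East-vs-west Welch tests for every offset day present (or given)."""
    if days is None:
        days = sorted(centred["offset_day"].unique())
    return pd.DataFrame([compare_directions(centred, d) for d in days])
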