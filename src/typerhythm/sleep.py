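"""Daily sleep duration from the typing-activity score matrix.

The component-1 score matrix is binarised: cells strictly below a threshold
are labelled asleep, everything else wakeful, and sleep labels are counted
per day. No contiguity is imposed, so split nights and daytime naps count
toward the daily total, and no assumption is made about when the person
sleeps (unrestricted chronotypes).

The binarisation threshold can be supplied manually or estimated from the
score histogram (Otsu's between-class-variance criterion, or the valley
between the two dominant modes of a kernel density estimate).
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from skimage.filters import threshold_otsu

from .sessions import ValidationError

#: Days with fewer observed hours than this are dropped by default in the
#: pipeline: extreme estimates tend to come from days with very little data.
DEFAULT_MIN_OBSERVED_HOURS = 4


def estimate_threshold(
    scores: np.ndarray,
    method: str = "otsu",
    value: float | None = None,
    kde_grid_size: int = 512,
    valley_prominence: float = 0.95,
) -> float:
    """Estimate the sleep/wake binarisation threshold from score values.

    Parameters
    ----------
    scores : ndarray
        Day-by-24 score matrix (or any array of score values).
    method : {'manual', 'otsu', 'valley', 'auto'}
        ``manual`` returns ``value`` unchanged. ``otsu`` maximises
        between-class variance of the score histogram. ``valley`` fits a
        Gaussian KDE and returns the density minimum between the two largest
        modes; it raises if the density is unimodal. ``auto`` tries the
        valley and falls back to Otsu on a unimodal density.
    value : float, optional
        The manual threshold (required for ``method='manual'``).
    """
    vals = np.asarray(scores, dtype=float).ravel()
    if not np.all(np.isfinite(vals)):
        raise ValidationError("score matrix must be finite")

    if method == "manual":
        if value is None or not np.isfinite(value):
            raise ValidationError("manual method requires a finite threshold value")
        return float(value)

    if method == "otsu":
        return float(threshold_otsu(vals))

    if method == "auto":
        try:
            return estimate_threshold(vals, "valley",
                                      kde_grid_size=kde_grid_size)
        except ValidationError:
            return float(threshold_otsu(vals))

    if method == "valley":
        kde = gaussian_kde(vals)
        lo, hi = vals.min(), vals.max()
        pad = 0.05 * (hi - lo)
        grid = np.linspace(lo - pad, hi + pad, kde_grid_size)
        dens = kde(grid)
        interior = np.flatnonzero(
            (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
        ) + 1
        unimodal_msg = (
            "score density is effectively unimodal; the valley method needs "
            "two prominent modes — use method='manual' or method='otsu'"
        )
        if len(interior) < 2:
            raise ValidationError(unimodal_msg)
        top2 = sorted(interior[np.argsort(dens[interior])[-2:]])
        between = slice(top2[0], top2[1] + 1)
        valley = float(dens[between].min())
        # Guard against sampling wiggles in the KDE: the dip between the two
        # modes must be genuinely prominent, not a ripple on one hump.
        if valley > valley_prominence * min(dens[top2[0]], dens[top2[1]]):
            raise ValidationError(unimodal_msg)
        return float(grid[between][np.argmin(dens[between])])

    raise ValidationError(f"unknown threshold method '{method}'")


def binarise_and_count(
    scores: np.ndarray,
    threshold: float,
    days: list[dt.date] | None = None,
    observed: np.ndarray | None = None,
) -> pd.DataFrame:
    """Classify cells below ``threshold`` as sleep and count them per day.

    The inequality is strict (score < threshold => sleep; ties are wakeful).
    Returns one row per day with columns ``date``, ``sleep_hours``,
    ``n_observed_hours`` (24 when no mask is given) and ``threshold_used``.
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    mat = np.asarray(scores, dtype=float)
    if mat.ndim != 2:
        raise ValidationError("scores must be a day-by-hour matrix")
    n_days = mat.shape[0]
    if days is None:
        days = list(range(n_days))
    if observed is None:
        n_obs = np.full(n_days, mat.shape[1], dtype=int)
    else:
        n_obs = np.asarray(observed, dtype=bool).sum(axis=1).astype(int)

    asleep = mat < threshold
    return pd.DataFrame({
        "date": [d.isoformat() if hasattr(d, "isoformat") else d for d in days],
        "sleep_hours": asleep.sum(axis=1).astype(int),
        "n_observed_hours": n_obs,
        "threshold_used": float(threshold),
    })


def filter_low_data_days(
    series: pd.DataFrame,
    min_observed_hours: int = DEFAULT_MIN_OBSERVED_HOURS,
) -> pd.DataFrame:
    """Drop days with fewer than ``min_observed_hours`` observed hours."""
    return series[series["n_observed_hours"] >= min_observed_hours].reset_index(
        drop=True
    )


def sleep_from_scores(
    scores: np.ndarray,
    days: list[dt.date] | None = None,
    observed: np.ndarray | None = None,
    method: str = "otsu",
    value: float | None = None,
    min_observed_hours: int = 0,
) -> pd.DataFrame:
    """Threshold estimation + binarisation + counting in one call."""
    thr = estimate_threshold(scores, method=method, value=value)
    series = binarise_and_count(scores, thr, days=days, observed=observed)
    if min_observed_hours > 0:
        series = filter_low_data_days(series, min_observed_hours)
    return series
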