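"""Session-level ingest and hourly aggregation.

Typing-session records (one row per continuous typing bout) are binned into
day-by-hour matrices of four modalities on a fixed UTC grid:

* ``median_ikd`` — median inter-key delay (ms) pooled over the hour's
  sessions; an inverse measure of typing speed,
* ``key_count`` — total key presses in the hour,
* ``upright_rate`` — fraction of sessions with the phone oriented upward,
* ``movement_rate`` — fraction of sessions with the phone non-stationary.

An hour with no sessions is *missing* in all four modalities rather than an
observed zero: absence of typing may mean sleep, and deciding which is the
job of the graph-regularised decomposition downstream, not the aggregator.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed modality order used throughout the package.
MODALITIES = ("median_ikd", "key_count", "upright_rate", "movement_rate")

#: Inter-key delays above this are pauses, not typing, and are discarded
#: before the hourly median.
PAUSE_THRESHOLD_MS = 5000.0


class ValidationError(ValueError):
    """Raised when input records violate the documented contract."""


@dataclass(frozen=True)
class SessionRecord:
    """One typing session.

    Parameters
    ----------
    start_time : datetime.datetime
        Timezone-aware session start; converted to UTC.
    utc_offset_min : int
        Local UTC offset in signed minutes, in [-720, +840], a multiple of 15.
    inter_key_delays : tuple of float
        Delays (ms) between consecutive alphanumeric key presses; all > 0.
    n_keypresses : int
        Number of key presses in the session (>= 0).
    upright : bool
        Phone oriented upward during the session.
    moving : bool
        Phone non-stationary during the session.
    """

    start_time: dt.datetime
    utc_offset_min: int
    inter_key_delays: tuple[float, ...]
    n_keypresses: int
    upright: bool
    moving: bool
    session_id: str | None = None

    def __post_init__(self) -> None:
        if self.start_time.tzinfo is None:
            raise ValidationError("start_time must be timezone-aware")
        object.__setattr__(
            self, "start_time", self.start_time.astimezone(dt.timezone.utc)
        )
        object.__setattr__(
            self, "inter_key_delays", tuple(float(d) for d in self.inter_key_delays)
        )
        if self.n_keypresses < 0:
            raise ValidationError("n_keypresses must be non-negative")
        if self.n_keypresses >= 2 and not self.inter_key_delays:
            raise ValidationError(
                "a session with >= 2 key presses must carry inter-key delays"
            )
        if any(d <= 0 for d in self.inter_key_delays):
            raise ValidationError("inter-key delays must be positive")
        if not (-12 * 60 <= self.utc_offset_min <= 14 * 60):
            raise ValidationError("utc_offset_min outside [-12 h, +14 h]")
        if self.utc_offset_min % 15 != 0:
            raise ValidationError("utc_offset_min must be a multiple of 15 minutes")


@dataclass
class ModalityTensor:
    """Four day-by-24-hour matrices sharing one observed-cell mask.

    ``values`` has shape (4, n_days, 24) in :data:`MODALITIES` order;
    ``observed`` has shape (n_days, 24) and applies to every modality: an
    hour with no sessions is missing everywhere. ``utc_offsets`` optionally
    carries the per-day local offset (minutes) as metadata for downstream
    time-zone analyses.
    """

    days: list[dt.date]
    values: np.ndarray
    observed: np.ndarray
    standardised: bool = False
    utc_offsets: dict[dt.date, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        n_days = len(self.days)
        if self.values.shape != (len(MODALITIES), n_days, 24):
            raise ValidationError(
                f"values must have shape (4, {n_days}, 24), got {self.values.shape}"
            )
        if self.observed.shape != (n_days, 24):
            raise ValidationError(f"observed must have shape ({n_days}, 24)")

    @property
    def n_days(self) -> int:
        return len(self.days)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectorise to a (4, 24*D) matrix and its shared (24*D,) column mask.

        Time bins are ordered row-major by (day, hour).
        """
        X = self.values.reshape(len(MODALITIES), -1)
        mask = self.observed.reshape(-1)
        return X, mask

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: (date, hour, modality, value, observed)."""
        rows = []
        for m, name in enumerate(MODALITIES):
            for d, day in enumerate(self.days):
                for h in range(24):
                    rows.append(
                        (day.isoformat(), h, name, self.values[m, d, h],
                         bool(self.observed[d, h]))
                    )
        return pd.DataFrame(
            rows, columns=["date", "hour", "modality", "value", "observed"]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ModalityTensor":
        days = sorted({dt.date.fromisoformat(str(s)) for s in frame["date"]})
        day_idx = {d: i for i, d in enumerate(days)}
        values = np.full((len(MODALITIES), len(days), 24), np.nan)
        observed = np.zeros((len(days), 24), dtype=bool)
        mod_idx = {name: m for m, name in enumerate(MODALITIES)}
        for row in frame.itertuples(index=False):
            d = day_idx[dt.date.fromisoformat(str(row.date))]
            h = int(row.hour)
            values[mod_idx[row.modality], d, h] = row.value
            observed[d, h] = bool(row.observed)
        return cls(days=days, values=values, observed=observed)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "ModalityTensor":
        return cls.from_frame(pd.read_csv(path))

    def save_npz(self, path) -> None:
        np.savez(
            path,
            days=np.array([d.isoformat() for d in self.days]),
            values=self.values,
            observed=self.observed,
            standardised=np.array(self.standardised),
        )

    @classmethod
    def load_npz(cls, path) -> "ModalityTensor":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                days=[dt.date.fromisoformat(str(s)) for s in z["days"]],
                values=z["values"],
                observed=z["observed"],
                standardised=bool(z["standardised"]),
            )


def _day_range(start: dt.date, end: dt.date) -> list[dt.date]:
    if end < start:
        raise ValidationError("grid end date precedes start date")
    return [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]


def aggregate_sessions(
    records: list[SessionRecord],
    grid: tuple[dt.date, dt.date] | list[dt.date] | None = None,
    pause_threshold_ms: float = PAUSE_THRESHOLD_MS,
) -> ModalityTensor:
    """Bin sessions into hourly day-by-hour modality matrices on a UTC grid.

    Each session is assigned to the UTC hour of its start time. Per observed
    (day, hour) cell: the median inter-key delay is taken over the *pooled*
    delays of that hour's sessions (delays above ``pause_threshold_ms`` are
    discarded first); key counts are summed; upright/movement rates are the
    fraction of sessions with the respective flag set.

    Parameters
    ----------
    records : list of SessionRecord
    grid : (start_date, end_date) or explicit date list, optional
        UTC day grid. Defaults to the span of the records. Records outside
        the grid are dropped with a logged count.

    Returns
    -------
    ModalityTensor
    """
    if not records:
        raise ValidationError("no session records provided")

    seen: set = set()
    for r in records:
        key = (r.start_time, r.inter_key_delays, r.n_keypresses, r.upright, r.moving)
        if r.session_id is not None:
            key = (r.session_id,)
        if key in seen:
            raise ValidationError(f"duplicate session record: {key}")
        seen.add(key)

    if grid is None:
        dates = [r.start_time.date() for r in records]
        days = _day_range(min(dates), max(dates))
    elif isinstance(grid, tuple):
        days = _day_range(*grid)
    else:
        days = sorted(grid)
    day_idx = {d: i for i, d in enumerate(days)}

    buckets: dict[tuple[int, int], list[SessionRecord]] = {}
    n_dropped = 0
    offsets: dict[dt.date, int] = {}
    for r in records:
        d = r.start_time.date()
        if d not in day_idx:
            n_dropped += 1
            continue
        buckets.setdefault((day_idx[d], r.start_time.hour), []).append(r)
        offsets[d] = r.utc_offset_min
    if n_dropped:
        logger.info("dropped %d records outside the day grid", n_dropped)
    if not buckets:
        raise ValidationError("no records fall inside the day grid")

    values = np.full((len(MODALITIES), len(days), 24), np.nan)
    observed = np.zeros((len(days), 24), dtype=bool)
    n_no_delay_cells = 0
    for (d, h), sess in buckets.items():
        pooled = [
            delay
            for s in sess
            for delay in s.inter_key_delays
            if delay <= pause_threshold_ms
        ]
        if not pooled:
            # No usable typing signal: treat the cell as missing everywhere,
            # consistent with the shared-mask contract.
            n_no_delay_cells += 1
            continue
        values[0, d, h] = float(np.median(pooled))
        values[1, d, h] = float(sum(s.n_keypresses for s in sess))
        values[2, d, h] = float(np.mean([s.upright for s in sess]))
        values[3, d, h] = float(np.mean([s.moving for s in sess]))
        observed[d, h] = True
    if n_no_delay_cells:
        logger.info(
            "masked %d cells whose sessions carried no usable inter-key delays",
            n_no_delay_cells,
        )

    return ModalityTensor(
        days=days, values=values, observed=observed, utc_offsets=offsets
    )


def standardise_modalities(tensor: ModalityTensor) -> ModalityTensor:
    """Z-score each modality over its observed cells; flip the sign of
    ``median_ikd`` so that, for every modality, larger means more active.

    The z-score uses the population denominator (ddof=0). Re-standardising an
    already standardised tensor is a no-op up to floating error (the sign
    flip is applied only once).

    Raises
    ------
    ValidationError
        If a modality has fewer than two observed cells or zero variance.
    """
    values = tensor.values.copy()
    mask = tensor.observed
    if mask.sum() < 2:
        raise ValidationError("need at least 2 observed cells to standardise")
    for m, name in enumerate(MODALITIES):
        obs = values[m][mask]
        sd = float(np.std(obs))
        if sd == 0.0:
            raise ValidationError(f"modality '{name}' has zero variance")
        values[m][mask] = (obs - float(np.mean(obs))) / sd
        if name == "median_ikd" and not tensor.standardised:
            values[m][mask] *= -1.0
    return replace(tensor, values=values, standardised=True)


# ---------------------------------------------------------------------------
# File I/O for the documented session schema
# ---------------------------------------------------------------------------

SESSION_COLUMNS = [
    "session_id", "start_time", "utc_offset_min", "ikd_ms",
    "n_keypresses", "upright", "moving",
]


def sessions_to_frame(records: list[SessionRecord]) -> pd.DataFrame:
    """Serialise records to the documented tabular schema.

    ``ikd_ms`` holds the delay list as a JSON array string, which survives
    both CSV and Parquet round-trips.
    """
    rows = []
    for i, r in enumerate(records):
        rows.append({
            "session_id": r.session_id if r.session_id is not None else str(i),
            "start_time": r.start_time.isoformat(),
            "utc_offset_min": r.utc_offset_min,
            "ikd_ms": json.dumps(list(r.inter_key_delays)),
            "n_keypresses": r.n_keypresses,
            "upright": int(r.upright),
            "moving": int(r.moving),
        })
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def frame_to_sessions(frame: pd.DataFrame) -> list[SessionRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(SessionRecord(
            start_time=dt.datetime.fromisoformat(str(row.start_time)),
            utc_offset_min=int(row.utc_offset_min),
            inter_key_delays=tuple(json.loads(row.ikd_ms)),
            n_keypresses=int(row.n_keypresses),
            upright=bool(int(row.upright)),
            moving=bool(int(row.moving)),
            session_id=str(row.session_id),
        ))
    return records


def write_sessions(records: list[SessionRecord], path) -> None:
    frame = sessions_to_frame(records)
    if str(path).endswith(".parquet"):
        frame.to_parquet(path, index=False)
    else:
        frame.to_csv(path, index=False)


def read_sessions(path) -> list[SessionRecord]:
    if str(path).endswith(".parquet"):
        frame = pd.read_parquet(path)
    else:
        frame = pd.read_csv(path)
    return frame_to_sessions(frame)
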