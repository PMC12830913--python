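"""Synthetic typing-session streams with known ground truth.

The generator emulates the data-generating assumptions behind the diurnal
framework: a per-user sleep-wake rhythm that is stable across days (a
chronotype), typing activity and speed that are modulated over the waking
day, hours without any typing while awake (wake missingness) and whole days
without data, and travel itineraries that shift the local clock and drag the
internal rhythm toward the new zone at a finite re-entrainment rate — with
eastward travel allowed to re-entrain more slowly than westward, as the
jet-lag literature suggests.

Alongside the session stream it returns exact per-UTC-day sleep hours and
the true activity phase, plus emulators for a wearable-style reference
(noisy nightly durations, naps excluded by default as ring devices typically
miss daytime naps) and a truncated hourly self-report scale whose maximal
response is "10+ hours".
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .sessions import SessionRecord


def _circ_diff_24(a: float, b: float) -> float:
    """Signed shortest difference a - b on a 24 h circle, in (-12, +12]."""
    d = (a - b) % 24.0
    return d if d <= 12.0 else d - 24.0


class UserScenario(BaseModel):
    """Parameters of one simulated user.

    Times are clock hours; offsets signed minutes; rates are probabilities.
    ``shift_schedule`` lists (day_index, new_utc_offset_min) pairs; the
    internal rhythm then moves toward the new local target at
    ``entrain_rate_east`` / ``entrain_rate_west`` hours per day (eastward
    re-entrainment is slower by default).
    """

    n_days: int = Field(default=60, ge=1)
    start_date: dt.date = dt.date(2024, 1, 6)
    chronotype_midsleep: float = Field(default=4.0, ge=0.0, lt=24.0)
    true_sleep_mean: float = Field(default=8.0, gt=0.0, lt=24.0)
    true_sleep_sd: float = Field(default=0.75, ge=0.0)
    wake_missingness: float = Field(default=0.2, ge=0.0, le=1.0)
    missing_day_prob: float = Field(default=0.02, ge=0.0, le=1.0)
    sessions_per_active_hour: float = Field(default=3.0, gt=0.0)
    activity_amplitude: float = Field(default=0.5, ge=0.0, le=1.0)
    activity_edge_power: float = Field(default=4.0, ge=1.0)
    night_check_prob: float = Field(default=0.15, ge=0.0, le=1.0)
    ikd_base_ms: float = Field(default=250.0, gt=0.0)
    diurnal_amplitude: float = Field(default=0.1, ge=0.0, lt=1.0)
    ikd_lognorm_sigma: float = Field(default=0.4, ge=0.0)
    ikd_session_sigma: float = Field(default=0.3, ge=0.0)
    keys_per_session_mean: float = Field(default=20.0, gt=0.0)
    upright_day: float = Field(default=0.8, ge=0.0, le=1.0)
    upright_night: float = Field(default=0.5, ge=0.0, le=1.0)
    movement_day: float = Field(default=0.3, ge=0.0, le=1.0)
    movement_night: float = Field(default=0.1, ge=0.0, le=1.0)
    nap_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    nap_hours: int = Field(default=1, ge=1, le=4)
    nap_clock: float = Field(default=14.5, ge=0.0, lt=24.0)
    base_utc_offset: int = 0
    shift_schedule: list[tuple[int, int]] = Field(default_factory=list)
    entrain_rate_east: float = Field(default=1.0, gt=0.0)
    entrain_rate_west: float = Field(default=1.5, gt=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _feasible_windows(self) -> "UserScenario":
        if self.true_sleep_mean + 3 * self.true_sleep_sd >= 24:
            raise ValueError(
                "infeasible sleep window: mean + 3 sd must stay below 24 h"
            )
        for day, off in self.shift_schedule:
            if not (0 <= day < self.n_days):
                raise ValueError("shift_schedule day index outside scenario")
            if not (-12 * 60 <= off <= 14 * 60) or off % 15 != 0:
                raise ValueError("shift_schedule offset invalid")
        return self


@dataclass
class SimulatedUser:
    """Output of :func:`simulate_user`.

    ``truth`` has one row per UTC day: integer ``night_sleep_hours`` and
    ``nap_hours`` (hour-grid counts), ``total_sleep_hours``,
    ``true_phase_hours`` (wake midpoint in UTC) and ``midsleep_utc``;
    ``offsets`` carries the per-day local UTC offset.
    """

    scenario: UserScenario
    records: list[SessionRecord]
    truth: pd.DataFrame
    offsets: pd.DataFrame


def _offset_series(sc: UserScenario) -> np.ndarray:
    offsets = np.full(sc.n_days, sc.base_utc_offset, dtype=int)
    for day, off in sorted(sc.shift_schedule):
        offsets[day:] = off
    return offsets


def _midsleep_track(sc: UserScenario, offsets: np.ndarray) -> np.ndarray:
    """Internal mid-sleep time (UTC hours) with finite re-entrainment."""
    targets = (sc.chronotype_midsleep - offsets / 60.0) % 24.0
    mid = np.empty(sc.n_days)
    mid[0] = targets[0]
    for d in range(1, sc.n_days):
        delta = _circ_diff_24(targets[d], mid[d - 1])
        # Positive delta = phase delay (westward shift), negative = advance
        # (eastward); the advance direction re-entrains more slowly.
        rate = sc.entrain_rate_west if delta > 0 else sc.entrain_rate_east
        if abs(delta) <= rate:
            mid[d] = targets[d]
        else:
            mid[d] = (mid[d - 1] + np.sign(delta) * rate) % 24.0
    return mid


def simulate_user(scenario: UserScenario) -> SimulatedUser:
    """Generate a session stream plus ground truth for one user.

    Per day, a sleep window of Gaussian-drawn duration is centred on the
    (possibly re-entraining) mid-sleep time; hour cells whose centre falls
    inside the window are asleep. Awake hours emit Poisson session counts,
    thinned by the wake-missingness probability, with the Poisson rate
    following a raised cosine over the waking day (people type less right
    after waking and before bed). Sessions carry lognormal inter-key delays
    whose median follows a diurnal performance curve (fastest mid-wake), and
    Bernoulli orientation/movement flags with different rates near the sleep
    boundary. Whole days are dropped with ``missing_day_prob``. Fixed seeds
    reproduce the output bit for bit.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n_hours = sc.n_days * 24

    offsets = _offset_series(sc)
    midsleep = _midsleep_track(sc, offsets)

    durations = np.clip(
        rng.normal(sc.true_sleep_mean, sc.true_sleep_sd, sc.n_days), 0.0, 24.0
    )
    missing_day = rng.random(sc.n_days) < sc.missing_day_prob
    nap_day = rng.random(sc.n_days) < sc.nap_prob

    asleep = np.zeros(n_hours, dtype=bool)
    napping = np.zeros(n_hours, dtype=bool)
    centres = np.arange(n_hours) + 0.5
    for d in range(sc.n_days):
        mid_abs = 24 * d + midsleep[d]
        half = durations[d] / 2.0
        lo, hi = mid_abs - half, mid_abs + half
        sel = (centres >= lo) & (centres < hi)
        asleep |= sel
        if nap_day[d]:
            nlo = 24 * d + sc.nap_clock - sc.nap_hours / 2.0
            sel = (centres >= nlo) & (centres < nlo + sc.nap_hours)
            napping |= sel & ~asleep

    records: list[SessionRecord] = []
    sid = 0
    for d in range(sc.n_days):
        if missing_day[d]:
            continue
        wake_mid = (midsleep[d] + 12.0) % 24.0
        half_wake = max((24.0 - durations[d]) / 2.0, 1e-6)
        for h in range(24):
            a = 24 * d + h
            if napping[a]:
                continue
            if asleep[a]:
                # Rare brief nocturnal phone check: one short, slow,
                # flat-in-bed session. The person is still asleep for the
                # hour as far as ground truth is concerned.
                if rng.random() >= sc.night_check_prob:
                    continue
                x, rate = 1.0, 0.0
                n_sessions = 1
                ikd_median = sc.ikd_base_ms * (1 + 2 * sc.diurnal_amplitude)
                p_up, p_mv = sc.upright_night, sc.movement_night
                minutes = rng.random(1) * 60.0
                keys_mean = max(sc.keys_per_session_mean / 4.0, 1.0)
            else:
                if rng.random() < sc.wake_missingness:
                    continue
                x = np.clip(
                    _circ_diff_24(h + 0.5, wake_mid) / half_wake, -1, 1
                )
                # Plateau with sharp edges: activity is sustained over the
                # waking day and only drops close to the sleep boundary.
                edge = abs(x) ** sc.activity_edge_power
                rate = sc.sessions_per_active_hour * (
                    1 - sc.activity_amplitude * edge
                )
                n_sessions = rng.poisson(rate)
                if n_sessions == 0:
                    continue
                ikd_median = sc.ikd_base_ms * (1 + sc.diurnal_amplitude * edge)
                p_up, p_mv = sc.upright_day, sc.movement_day
                minutes = np.sort(rng.random(n_sessions)) * 60.0
                keys_mean = sc.keys_per_session_mean
            for j in range(n_sessions):
                n_keys = 2 + rng.poisson(keys_mean)
                # Between-session context factor: what is being typed moves
                # the whole session's tempo far more than time of day does.
                session_factor = np.exp(
                    rng.normal(0.0, sc.ikd_session_sigma)
                )
                delays = ikd_median * session_factor * np.exp(
                    rng.normal(0.0, sc.ikd_lognorm_sigma, n_keys - 1)
                )
                start = (
                    dt.datetime.combine(
                        sc.start_date + dt.timedelta(days=d),
                        dt.time(0, 0),
                        tzinfo=dt.timezone.utc,
                    )
                    + dt.timedelta(hours=h)
                    + dt.timedelta(minutes=float(minutes[j]))
                )
                records.append(SessionRecord(
                    start_time=start,
                    utc_offset_min=int(offsets[d]),
                    inter_key_delays=tuple(np.round(delays, 3)),
                    n_keypresses=n_keys,
                    upright=bool(rng.random() < p_up),
                    moving=bool(rng.random() < p_mv),
                    session_id=f"s{sid:06d}",
                ))
                sid += 1

    dates = [sc.start_date + dt.timedelta(days=d) for d in range(sc.n_days)]
    night = asleep.reshape(sc.n_days, 24).sum(axis=1)
    naps = napping.reshape(sc.n_days, 24).sum(axis=1)
    truth = pd.DataFrame({
        "date": [d.isoformat() for d in dates],
        "night_sleep_hours": night.astype(int),
        "nap_hours": naps.astype(int),
        "total_sleep_hours": (night + naps).astype(int),
        "true_phase_hours": (midsleep + 12.0) % 24.0,
        "midsleep_utc": midsleep,
        "missing_day": missing_day,
    })
    offsets_df = pd.DataFrame({
        "date": [d.isoformat() for d in dates],
        "utc_offset_min": offsets,
    })
    return SimulatedUser(
        scenario=sc, records=records, truth=truth, offsets=offsets_df
    )


def simulate_wearable(
    truth: pd.DataFrame,
    noise_sd: float = 0.5,
    record_naps: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Wearable-style nightly sleep reference: truth plus Gaussian noise.

    Daytime naps are excluded unless ``record_naps`` is set, mirroring ring
    devices that only score bedtime sleep. Values are clipped to [0, 24].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = truth["night_sleep_hours"].to_numpy(dtype=float)
    if record_naps:
        base = base + truth["nap_hours"].to_numpy(dtype=float)
    vals = np.clip(base + rng.normal(0.0, noise_sd, base.size), 0.0, 24.0)
    return pd.DataFrame({
        "date": truth["date"].to_numpy(),
        "wearable_sleep_hours": vals,
    })


def simulate_selfreport(
    truth: pd.DataFrame,
    noise_sd: float = 0.0,
    attrition: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Hourly Likert self-report: rounded, top-coded at "10+ hours".

    Optional Gaussian reporting noise is added before rounding; responses go
    missing (NaN) independently with probability ``attrition``.
    """
    rng = np.random.default_rng(seed)
    base = truth["night_sleep_hours"].to_numpy(dtype=float)
    noisy = base + rng.normal(0.0, noise_sd, base.size) if noise_sd > 0 else base
    likert = np.clip(np.round(noisy), 0, 10)
    missing = rng.random(base.size) < attrition
    likert = np.where(missing, np.nan, likert)
    return pd.DataFrame({
        "date": truth["date"].to_numpy(),
        "selfreport_hours": likert,
    })


def lowrank_diurnal_matrix(
    n_days: int = 40,
    seed: int = 0,
    noise_sd: float = 0.2,
    observed_frac: float = 0.8,
    phase_walk_sd: float = 0.5,
    amp_walk_sd: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, list[dt.date]]:
    """Rank-one modality-by-timebin matrix with a smooth diurnal time factor.

    The shared time factor is a 24 h sinusoid whose phase and amplitude drift
    slowly from day to day (bounded random walks), plus white noise — the
    regime the graph penalty is designed for: smooth along hours and across
    the same hour on adjacent days, but not identical across days. A random
    ``observed_frac`` of time bins is observed (column-shared mask).

    Returns (X, col_mask, days) ready for :class:`typerhythm.GRSVD`.
    """
    rng = np.random.default_rng(seed)
    u = np.array([0.55, 0.6, 0.4, 0.42])
    u /= np.linalg.norm(u)
    phase = np.cumsum(rng.normal(0.0, phase_walk_sd, n_days))
    amp = 1.0 + np.clip(np.cumsum(rng.normal(0.0, amp_walk_sd, n_days)),
                        -0.5, 0.5)
    hours = np.arange(24)
    v = np.concatenate([
        amp[d] * np.cos(2 * np.pi * (hours - 14 - phase[d]) / 24)
        for d in range(n_days)
    ])
    X = 3.0 * np.outer(u, v) + rng.normal(0.0, noise_sd, (4, 24 * n_days))
    col_mask = rng.random(24 * n_days) < observed_frac
    days = [dt.date(2024, 1, 1) + dt.timedelta(days=i) for i in range(n_days)]
    return X, col_mask, days


def make_cohort(
    base: UserScenario,
    n_users: int,
    chronotype_sd: float = 1.5,
    sleep_mean_sd: float = 0.6,
    seed: int = 0,
) -> list[UserScenario]:
    """Compose single-user scenarios into a cohort with per-user random
    effects on chronotype and mean sleep duration."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_users):
        out.append(base.model_copy(update={
            "chronotype_midsleep": float(
                (base.chronotype_midsleep + rng.normal(0, chronotype_sd)) % 24
            ),
            "true_sleep_mean": float(np.clip(
                base.true_sleep_mean + rng.normal(0, sleep_mean_sd), 3.0, 12.0
            )),
            "seed": int(rng.integers(0, 2**31 - 1)),
        }))
    return out
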