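"""End-to-end runs: aggregate -> graph -> GRSVD -> sleep + phase -> reports.

A run is fully described by a :class:`RunConfig`; given the same config and
inputs the summary JSON is byte-identical across reruns. All module outputs
are written as UTF-8 CSV/JSON under the configured output directory.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from . import __version__
from .grsvd import GRSVD, select_lambda
from .phase import (
    centred_transition_table,
    daily_phase,
    detect_transitions,
    direction_test_table,
)
from .sessions import (
    SessionRecord,
    ValidationError,
    aggregate_sessions,
    read_sessions,
    standardise_modalities,
)
from .sleep import estimate_threshold, binarise_and_count, filter_low_data_days
from .timegraph import build_time_graph, laplacian

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure with a machine-readable stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class RunConfig(BaseModel):
    """Serialisable description of one pipeline run.

    ``lam=None`` invokes the built-in re-masking heuristic for the smoothing
    weight; a number mirrors hand optimisation of the hyperparameter.
    """

    sessions_path: str | None = None
    reference_path: str | None = None
    grid_start: dt.date | None = None
    grid_end: dt.date | None = None
    lam: float | None = None
    rank: int = Field(default=1, ge=1)
    tol: float = Field(default=1e-8, gt=0)
    max_iter: int = Field(default=500, ge=1)
    threshold_method: str = "auto"
    threshold_value: float | None = None
    weight_transform: str = "clip"
    min_observed_hours: int = Field(default=4, ge=0)
    min_persist: int = Field(default=7, ge=1)
    pre_days: int = Field(default=3, ge=1)
    post_days: int = Field(default=7, ge=1)
    min_magnitude_hours: float = Field(default=0.0, ge=0.0)
    seed: int = 0
    out_dir: str = "run_output"

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.model_validate_json(text)


def compare_to_reference(
    estimates: pd.DataFrame,
    reference: pd.DataFrame,
    est_col: str | None = None,
    ref_col: str | None = None,
) -> dict:
    """Spearman's rank correlation (mid-ranks for ties), RMSE and MAE
    between two per-day series, inner-joined on date.

    Fewer than three paired days yields ``computable=False``.
    """
    est_col = est_col or [c for c in estimates.columns if c != "date"][0]
    ref_col = ref_col or [c for c in reference.columns if c != "date"][0]
    merged = pd.merge(
        estimates[["date", est_col]], reference[["date", ref_col]], on="date"
    ).dropna()
    n = len(merged)
    if n < 3:
        return {"computable": False, "n": int(n),
                "spearman_rho": np.nan, "rmse": np.nan, "mae": np.nan}
    a = merged[est_col].to_numpy(dtype=float)
    b = merged[ref_col].to_numpy(dtype=float)
    rho = stats.spearmanr(a, b).statistic
    err = a - b
    return {
        "computable": True,
        "n": int(n),
        "spearman_rho": float(rho),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
    }


def model_ready_table(
    estimates: pd.DataFrame,
    reference: pd.DataFrame,
    user: str = "user0",
) -> pd.DataFrame:
    """Long table (user, date, estimate_std, reference) for downstream
    mixed-effects modelling in standard statistical tooling; the estimate is
    standardised across all observations."""
    merged = pd.merge(
        estimates.rename(columns={estimates.columns[1]: "estimate"}),
        reference.rename(columns={reference.columns[1]: "reference"}),
        on="date",
    ).dropna()
    est = merged["estimate"].to_numpy(dtype=float)
    sd = est.std()
    merged["estimate_std"] = (est - est.mean()) / sd if sd > 0 else 0.0
    merged.insert(0, "user", user)
    return merged[["user", "date", "estimate_std", "reference"]]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(
    config: RunConfig,
    records: list[SessionRecord] | None = None,
    offsets: pd.DataFrame | None = None,
    reference: pd.DataFrame | None = None,
    write: bool = True,
) -> dict:
    """Execute the full pipeline and return (and optionally write) all
    artefacts.

    Inputs may be passed in memory or read from the configured paths.
    Returns a dict with the tensor, graph, results object, sleep and phase
    tables, transition analysis (when offsets are available) and the summary
    dict that is serialised to ``summary.json``.
    """
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    if records is None:
        if config.sessions_path is None:
            raise PipelineError("ingest", "no session records or path given")
        records = _stage("ingest")(read_sessions)(config.sessions_path)

    grid = None
    if config.grid_start is not None and config.grid_end is not None:
        grid = (config.grid_start, config.grid_end)
    tensor = _stage("aggregate")(aggregate_sessions)(records, grid=grid)
    std = _stage("standardise")(standardise_modalities)(tensor)

    graph = _stage("graph")(build_time_graph)(std.days)
    L = laplacian(graph)
    X, mask = std.stacked()

    lam = config.lam
    if lam is None:
        lam = _stage("lambda")(select_lambda)(X, mask, L, seed=config.seed)
        logger.info("selected lambda = %g by re-masking heuristic", lam)

    model = GRSVD(X=X, col_mask=mask, L=L, lam=lam, rank=config.rank,
                  days=std.days)
    result = _stage("grsvd")(model.fit)(
        tol=config.tol, max_iter=config.max_iter, seed=config.seed
    )

    scores = result.score_matrix()
    threshold = _stage("sleep")(estimate_threshold)(
        scores, method=config.threshold_method, value=config.threshold_value
    )
    sleep_all = binarise_and_count(
        scores, threshold, days=std.days, observed=std.observed
    )
    sleep_series = filter_low_data_days(sleep_all, config.min_observed_hours)

    phases = _stage("phase")(daily_phase)(
        scores, days=std.days, weight_transform=config.weight_transform
    )

    if offsets is None and std.utc_offsets:
        known = {d: o for d, o in std.utc_offsets.items()}
        vals = pd.Series(
            [known.get(d) for d in std.days], dtype="float"
        ).ffill().bfill()
        offsets = pd.DataFrame({
            "date": [d.isoformat() for d in std.days],
            "utc_offset_min": vals.astype(int),
        })

    transitions, centred, tests = [], None, None
    if offsets is not None:
        transitions = _stage("transitions")(detect_transitions)(
            offsets, min_persist=config.min_persist,
            min_magnitude_hours=config.min_magnitude_hours,
        )
        centred = centred_transition_table(
            phases, transitions, config.pre_days, config.post_days
        )
        if len(centred):
            tests = direction_test_table(centred)

    comparison = None
    if reference is None and config.reference_path is not None:
        reference = pd.read_csv(config.reference_path)
    if reference is not None:
        comparison = compare_to_reference(
            sleep_series[["date", "sleep_hours"]], reference
        )

    summary = {
        "version": __version__,
        "seed": config.seed,
        "lambda": float(lam),
        "n_days": len(std.days),
        "n_records": len(records),
        "threshold": float(threshold),
        "converged": bool(result.converged),
        "sleep": {
            r["date"]: int(r["sleep_hours"])
            for _, r in sleep_series.iterrows()
        },
        "phase": {
            r["date"]: (round(float(r["phase_hours"]), 6)
                        if r["defined"] else None)
            for _, r in phases.iterrows()
        },
        "n_transitions": len(transitions),
        "direction_tests": (
            [
                {k: (round(v, 6) if isinstance(v, float) and np.isfinite(v)
                     else (v if not isinstance(v, float) else None))
                 for k, v in row.items()}
                for row in tests.to_dict("records")
            ]
            if tests is not None else []
        ),
        "reference_comparison": (
            {k: (round(v, 6) if isinstance(v, float) and np.isfinite(v) else v)
             for k, v in comparison.items()}
            if comparison is not None else None
        ),
    }

    if write:
        std.save_csv(out / "modality_tensor.csv")
        graph.to_edge_list_frame().to_csv(out / "time_graph_edges.csv",
                                          index=False)
        result.save(out / "grsvd_scores.csv", out / "grsvd_diagnostics.json")
        sleep_series.to_csv(out / "sleep_series.csv", index=False)
        phases.to_csv(out / "phase_series.csv", index=False)
        if centred is not None and len(centred):
            centred.to_csv(out / "transition_centred_phases.csv", index=False)
        if tests is not None:
            tests.to_csv(out / "direction_tests.csv", index=False)
        (out / "config.json").write_text(config.to_json(), encoding="utf-8")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
        )

    return {
        "tensor": std,
        "graph": graph,
        "result": result,
        "sleep": sleep_series,
        "phases": phases,
        "transitions": transitions,
        "centred": centred,
        "direction_tests": tests,
        "comparison": comparison,
        "summary": summary,
    }
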