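"""Graph-regularised SVD of stacked modality matrices with missing entries.

The model factorises a modality-by-timebin matrix ``X`` (4 x 24*D) as a sum
of rank-one components ``sigma_k * u_k v_k^T`` where the time factor is
smoothed along a temporal graph. Component ``k`` is fitted to the current
residual ``R`` by minimising

    F(u, w) = sum_{(m,t) observed} (R_mt - u_m w_t)^2  +  lambda * w^T L w

over unit-norm modality loadings ``u`` (||u|| = 1) and a free scaled time
factor ``w`` (= sigma * v), where ``L`` is the graph Laplacian. Only observed
cells enter the fit term; the Laplacian penalty propagates information into
unobserved bins (selective imputation). The penalty acts on the scaled
factor: penalising the unit-norm factor instead would make the objective
degenerate under rescaling of the (u, v) pair.

Because the observation mask is shared across modalities (an hour with no
sessions is missing in every modality), both alternating updates are exact
coordinate minimisers:

* ``u`` <- c / ||c|| with c_m = sum_{t obs} R_mt w_t  (the masked column sums
  sum_{m obs} u_m^2 are identical across t, so the unit-sphere least-squares
  problem has this closed form),
* ``w`` <- solve[(diag(mask) + lambda L) w = b] with b_t = mask_t *
  sum_m u_m R_mt; the system matrix does not depend on u and is factorised
  once per fit.

Hence the objective trace is non-increasing, and with lambda = 0 on fully
observed data the iteration is power iteration: component 1 converges to the
leading singular triplet of X.
"""

from __future__ import annotations

import datetime as dt
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .sessions import MODALITIES, ModalityTensor, ValidationError
from .timegraph import TimeGraph, build_time_graph, laplacian

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 500
DEFAULT_SIGN_ANCHOR = "key_count"


def grsvd_objective(
    u: np.ndarray,
    w: np.ndarray,
    R: np.ndarray,
    col_mask: np.ndarray,
    L: sp.spmatrix,
    lam: float,
) -> float:
    """Evaluate F(u, w) — exposed so independent minimisers can target the
    identical objective."""
    resid = (R - np.outer(u, w))[:, col_mask]
    return float(np.sum(resid**2) + lam * (w @ (L @ w)))


@dataclass
class GRSVDProblem:
    """A masked decomposition problem.

    ``X`` is modality-by-timebin (4 x 24*D), vectorised row-major by
    (day, hour); ``col_mask`` is the shared observation pattern over time
    bins; ``L`` the time-graph Laplacian; ``lam`` the smoothing weight.
    """

    X: np.ndarray
    col_mask: np.ndarray
    L: sp.spmatrix
    lam: float
    rank: int = 1

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.col_mask = np.asarray(self.col_mask, dtype=bool)
        if self.X.ndim != 2:
            raise ValidationError("X must be 2-D (modalities x time bins)")
        n_mod, n_t = self.X.shape
        if self.col_mask.shape != (n_t,):
            raise ValidationError("col_mask length must match X columns")
        if self.L.shape != (n_t, n_t):
            raise ValidationError("Laplacian shape must match X columns")
        if self.lam < 0:
            raise ValidationError("lambda must be >= 0")
        if self.rank < 1:
            raise ValidationError("rank must be >= 1")
        if not np.all(np.isfinite(self.X[:, self.col_mask])):
            raise ValidationError("X must be finite on observed cells")


def _fit_component(
    R: np.ndarray,
    col_mask: np.ndarray,
    L: sp.spmatrix,
    lam: float,
    tol: float,
    max_iter: int,
    solver,
    w0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, int]:
    """Alternating exact minimisation for one component on residual R.

    Returns (u, w, objective_trace, converged, n_iter).
    """
    n_mod, n_t = R.shape
    Rm = np.where(col_mask[None, :], R, 0.0)

    if w0 is None:
        # Per-bin mean of observed values; zero where never observed.
        w = np.where(col_mask, Rm.mean(axis=0), 0.0)
    else:
        w = np.asarray(w0, dtype=float).copy()
    c = Rm @ w
    norm_c = np.linalg.norm(c)
    if norm_c == 0.0:
        # Degenerate residual (e.g. fully deflated); return a zero component.
        u = np.zeros(n_mod)
        u[0] = 1.0
        w = np.zeros(n_t)
        obj = grsvd_objective(u, w, R, col_mask, L, lam)
        return u, w, np.array([obj]), True, 0
    u = c / norm_c

    trace = [grsvd_objective(u, w, R, col_mask, L, lam)]
    converged = False
    it = 0
    # Near the optimum the objective is flat in the factors (quadratic in the
    # parameter error), so an objective-only stop can leave the factors an
    # order of magnitude less accurate than tol suggests; require the time
    # factor to be stationary as well.
    w_tol = np.sqrt(tol) / 10.0
    for it in range(1, max_iter + 1):
        b = col_mask * (u @ Rm)
        w_new = solver(b)
        w_change = np.linalg.norm(w_new - w) / max(np.linalg.norm(w_new),
                                                   1e-300)
        w = w_new
        c = Rm @ w
        norm_c = np.linalg.norm(c)
        if norm_c == 0.0:
            w = np.zeros(n_t)
            trace.append(grsvd_objective(u, w, R, col_mask, L, lam))
            converged = True
            break
        u = c / norm_c
        trace.append(grsvd_objective(u, w, R, col_mask, L, lam))
        denom = abs(trace[-2]) if trace[-2] != 0 else 1.0
        if abs(trace[-2] - trace[-1]) / denom < tol and w_change < w_tol:
            converged = True
            break
    return u, w, np.asarray(trace), converged, it


class GRSVD:
    """Masked graph-regularised SVD model.

    Parameters
    ----------
    X : ndarray, shape (n_modalities, n_bins)
        Standardised modality values, vectorised row-major by (day, hour).
        Unobserved entries may be NaN.
    col_mask : ndarray of bool, shape (n_bins,)
        Shared observation pattern (True where the hour has data).
    L : sparse matrix
        Time-graph Laplacian over the bins.
    lam : float
        Smoothing weight (>= 0). The method's one key hyperparameter; see
        :func:`select_lambda` for the built-in re-masking heuristic.
    rank : int
        Number of components, fitted by deflation.
    days : list of date, optional
        Day labels used to reshape scores back to day-by-24 form.

    Examples
    --------
    >>> model = GRSVD.from_tensor(std_tensor, lam=1.0)   # doctest: +SKIP
    >>> res = model.fit()                                # doctest: +SKIP
    >>> res.score_matrix().shape                         # doctest: +SKIP
    (60, 24)
    """

    def __init__(
        self,
        X: np.ndarray,
        col_mask: np.ndarray,
        L: sp.spmatrix,
        lam: float = 1.0,
        rank: int = 1,
        days: list[dt.date] | None = None,
        sign_anchor: str = DEFAULT_SIGN_ANCHOR,
        modality_names: tuple[str, ...] = MODALITIES,
    ) -> None:
        self.problem = GRSVDProblem(
            X=X, col_mask=np.asarray(col_mask, dtype=bool), L=L,
            lam=float(lam), rank=int(rank),
        )
        self.days = days
        self.modality_names = tuple(modality_names)
        if sign_anchor not in self.modality_names:
            raise ValidationError(f"unknown sign anchor modality '{sign_anchor}'")
        self.sign_anchor = sign_anchor

    @classmethod
    def from_tensor(
        cls,
        tensor: ModalityTensor,
        graph: TimeGraph | None = None,
        lam: float = 1.0,
        rank: int = 1,
        sign_anchor: str = DEFAULT_SIGN_ANCHOR,
    ) -> "GRSVD":
        """Build the model from a standardised :class:`ModalityTensor`.

        The time graph defaults to the spiral-with-crosslinks graph over the
        tensor's day grid.
        """
        if not tensor.standardised:
            warnings.warn(
                "tensor is not standardised; modalities with incommensurate "
                "units will dominate the decomposition",
                stacklevel=2,
            )
        if graph is None:
            graph = build_time_graph(tensor.days)
        X, mask = tensor.stacked()
        return cls(
            X=X, col_mask=mask, L=laplacian(graph), lam=lam, rank=rank,
            days=tensor.days, sign_anchor=sign_anchor,
        )

    def fit(
        self,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        seed: int | None = None,
        n_restarts: int = 0,
    ) -> "GRSVDResults":
        """Fit all components by deflation.

        The default initialisation (per-bin observed mean) is deterministic;
        ``seed`` only matters when ``n_restarts`` > 0, which adds random
        restarts and keeps the best objective.
        """
        if tol <= 0:
            raise ValidationError("tol must be positive")
        p = self.problem
        mask = p.col_mask
        if p.lam == 0.0 and not mask.all():
            raise ValidationError(
                "lambda = 0 with time bins unobserved in every modality makes "
                "the time-factor system singular; use lambda > 0 or drop the "
                "empty bins"
            )
        A = (sp.diags(mask.astype(float)) + p.lam * p.L).tocsc()
        lu = splu(A)
        solver = lu.solve

        rng = np.random.default_rng(seed)
        anchor = self.modality_names.index(self.sign_anchor)

        R = np.where(mask[None, :], np.nan_to_num(p.X), 0.0)
        us, sigmas, vs, traces = [], [], [], []
        converged_all = True
        total_iter = 0
        for _ in range(p.rank):
            best = _fit_component(R, mask, p.L, p.lam, tol, max_iter, solver)
            for _ in range(n_restarts):
                w0 = rng.standard_normal(R.shape[1])
                cand = _fit_component(
                    R, mask, p.L, p.lam, tol, max_iter, solver, w0=w0
                )
                if cand[2][-1] < best[2][-1]:
                    best = cand
            u, w, trace, conv, it = best
            if u[anchor] < 0:
                u, w = -u, -w
            sigma = float(np.linalg.norm(w))
            v = w / sigma if sigma > 0 else np.zeros_like(w)
            us.append(u)
            sigmas.append(sigma)
            vs.append(v)
            traces.append(trace)
            converged_all &= conv
            total_iter += it
            R = R - np.where(mask[None, :], sigma * np.outer(u, v), 0.0)

        if not converged_all:
            warnings.warn(
                "GRSVD did not converge within max_iter; results returned "
                "with converged=False",
                stacklevel=2,
            )
        return GRSVDResults(
            model=self,
            loadings=np.vstack(us),
            sigmas=np.asarray(sigmas),
            time_factors=np.vstack(vs),
            objective_traces=traces,
            converged=converged_all,
            n_iter=total_iter,
        )


@dataclass
class GRSVDResults:
    """Fitted decomposition.

    ``loadings[k]`` is the unit-norm modality loading vector of component
    k+1, ``sigmas[k]`` its non-negative scale and ``time_factors[k]`` the
    unit-norm time factor; ``score_matrix()`` reshapes ``sigma_1 * v_1`` to
    day-by-24 form — the typing-activity score used by the sleep and phase
    analyses, defined at every cell including imputed ones.
    """

    model: GRSVD
    loadings: np.ndarray
    sigmas: np.ndarray
    time_factors: np.ndarray
    objective_traces: list[np.ndarray] = field(repr=False)
    converged: bool
    n_iter: int

    @property
    def rank(self) -> int:
        return len(self.sigmas)

    def score_vector(self, component: int = 1) -> np.ndarray:
        if not 1 <= component <= self.rank:
            raise ValidationError(
                f"component must be in 1..{self.rank}, got {component}"
            )
        k = component - 1
        return self.sigmas[k] * self.time_factors[k]

    def score_matrix(self, component: int = 1) -> np.ndarray:
        """Day-by-24 score matrix of the given component (1-based)."""
        vec = self.score_vector(component)
        return vec.reshape(-1, 24)

    def smoothness_penalty(self, component: int = 1) -> float:
        w = self.score_vector(component)
        return float(w @ (self.model.problem.L @ w))

    def fitted_matrix(self) -> np.ndarray:
        """Low-rank reconstruction over all bins (observed and imputed)."""
        return (self.loadings.T * self.sigmas) @ self.time_factors

    # -- downstream conveniences ------------------------------------------
    def sleep_series(self, **kwargs) -> pd.DataFrame:
        """Per-day sleep-duration estimates; see :mod:`typerhythm.sleep`."""
        from . import sleep

        return sleep.sleep_from_scores(
            self.score_matrix(), days=self.model.days,
            observed=self._observed_matrix(), **kwargs,
        )

    def phase_series(self, **kwargs) -> pd.DataFrame:
        """Per-day activity phase; see :mod:`typerhythm.phase`."""
        from . import phase

        return phase.daily_phase(
            self.score_matrix(), days=self.model.days, **kwargs
        )

    def _observed_matrix(self) -> np.ndarray:
        return self.model.problem.col_mask.reshape(-1, 24)

    def to_frame(self) -> pd.DataFrame:
        """Long-format scores: (date, hour, component, score)."""
        days = self.model.days
        if days is None:
            days = list(range(self.time_factors.shape[1] // 24))
        rows = []
        for k in range(self.rank):
            mat = self.score_matrix(k + 1)
            for d, day in enumerate(days):
                label = day.isoformat() if hasattr(day, "isoformat") else day
                for h in range(24):
                    rows.append((label, h, k + 1, mat[d, h]))
        return pd.DataFrame(rows, columns=["date", "hour", "component", "score"])

    def diagnostics(self) -> dict:
        return {
            "lambda": self.model.problem.lam,
            "rank": self.rank,
            "sigmas": self.sigmas.tolist(),
            "loadings": {
                name: self.loadings[:, m].tolist()
                for m, name in enumerate(self.model.modality_names)
            },
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "final_objectives": [float(t[-1]) for t in self.objective_traces],
            "smoothness_penalty_c1": self.smoothness_penalty(1),
        }

    def save(self, scores_csv, sidecar_json) -> None:
        self.to_frame().to_csv(scores_csv, index=False)
        with open(sidecar_json, "w") as fh:
            json.dump(self.diagnostics(), fh, indent=2, sort_keys=True)

    def summary(self) -> str:
        """Plain-text summary table of the decomposition."""
        lines = [
            "Graph-regularised SVD results",
            "=" * 64,
            f"bins: {self.time_factors.shape[1]}  "
            f"observed: {int(self.model.problem.col_mask.sum())}  "
            f"lambda: {self.model.problem.lam:g}  rank: {self.rank}",
            f"converged: {self.converged}  iterations: {self.n_iter}",
            "-" * 64,
            f"{'modality':<16}" + "".join(
                f"{'u_' + str(k + 1):>12}" for k in range(self.rank)
            ),
        ]
        for m, name in enumerate(self.model.modality_names):
            lines.append(
                f"{name:<16}" + "".join(
                    f"{self.loadings[k, m]:>12.4f}" for k in range(self.rank)
                )
            )
        lines.append("-" * 64)
        lines.append(
            f"{'sigma':<16}" + "".join(
                f"{s:>12.4f}" for s in self.sigmas
            )
        )
        lines.append(
            f"{'penalty wLw':<16}" + "".join(
                f"{self.smoothness_penalty(k + 1):>12.4f}"
                for k in range(self.rank)
            )
        )
        return "\n".join(lines)


def hour_mean_impute(X: np.ndarray, col_mask: np.ndarray) -> np.ndarray:
    """Per-hour-of-day mean imputation baseline.

    For each modality and clock hour, unobserved bins receive the mean of the
    observed bins at the same hour of day (falling back to the modality's
    global observed mean for hours never observed).
    """
    n_mod, n_t = X.shape
    out = np.where(col_mask[None, :], np.nan_to_num(X), np.nan)
    hours = np.arange(n_t) % 24
    for m in range(n_mod):
        global_mean = np.nanmean(out[m]) if np.isfinite(out[m]).any() else 0.0
        for h in range(24):
            sel = hours == h
            vals = out[m, sel]
            fill = np.nanmean(vals) if np.isfinite(vals).any() else global_mean
            out[m, sel] = np.where(np.isfinite(vals), vals, fill)
    return out


def remask_rmse(
    X: np.ndarray,
    col_mask: np.ndarray,
    L: sp.spmatrix,
    lam: float,
    holdout_frac: float = 0.2,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[float, float]:
    """Hold out a fraction of observed time bins, refit, and score imputation.

    Whole bins (columns) are re-masked so the shared-mask contract holds.
    Returns (grsvd_rmse, hour_mean_rmse) on the held-out cells.
    """
    rng = np.random.default_rng(seed)
    obs_idx = np.flatnonzero(col_mask)
    n_hold = max(1, int(round(holdout_frac * obs_idx.size)))
    held = rng.choice(obs_idx, size=n_hold, replace=False)
    train_mask = col_mask.copy()
    train_mask[held] = False

    model = GRSVD(X=X, col_mask=train_mask, L=L, lam=lam, rank=1)
    res = model.fit(tol=tol, max_iter=max_iter)
    pred = res.fitted_matrix()
    truth = X[:, held]
    grsvd_rmse = float(np.sqrt(np.mean((pred[:, held] - truth) ** 2)))

    baseline = hour_mean_impute(X, train_mask)
    base_rmse = float(np.sqrt(np.mean((baseline[:, held] - truth) ** 2)))
    return grsvd_rmse, base_rmse


def select_lambda(
    X: np.ndarray,
    col_mask: np.ndarray,
    L: sp.spmatrix,
    grid: np.ndarray | None = None,
    holdout_frac: float = 0.2,
    seed: int = 0,
    n_folds: int = 3,
) -> float:
    """Re-masking heuristic for the smoothing weight.

    Returns the smallest lambda on a log grid whose held-out imputation RMSE
    (averaged over ``n_folds`` random re-masks) is within numerical tolerance
    of the grid minimum — a built-in stand-in for hand optimisation of the
    hyperparameter.
    """
    if grid is None:
        grid = np.logspace(-2, 2, 9)
    rng = np.random.default_rng(seed)
    fold_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_folds)]
    rmses = [
        float(np.mean([
            remask_rmse(X, col_mask, L, lam, holdout_frac=holdout_frac,
                        seed=s)[0]
            for s in fold_seeds
        ]))
        for lam in grid
    ]
    best = min(rmses)
    for lam, r in zip(grid, rmses):
        if r <= best * (1 + 1e-9):
            return float(lam)
    return float(grid[int(np.argmin(rmses))])
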