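"""Temporal graph over (day, hour) cells.

The graph encodes the assumption of a slowly varying, day-stable rhythm:
every hour is linked to the previous and next hour (including the wrap from
23:00 to the next day's 00:00) and to the same hour on the previous and next
calendar day — a spiral with crosslinks. Days absent from the grid break all
links across the gap, so a missing day disconnects the graph and stops
information flowing between the flanking stretches.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .sessions import ValidationError


@dataclass
class TimeGraph:
    """Undirected unit-weight graph over 24 hour-nodes per listed day.

    Nodes are ordered row-major by (day, hour); node ``24*j + i`` is hour
    ``i`` of ``days[j]``.
    """

    days: list[dt.date]
    adjacency: sp.csr_matrix

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def n_components(self) -> int:
        n, _ = connected_components(self.adjacency, directed=False)
        return int(n)

    def component_labels(self) -> np.ndarray:
        _, labels = connected_components(self.adjacency, directed=False)
        return labels

    def node_index(self, day: dt.date, hour: int) -> int:
        return 24 * self.days.index(day) + hour

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    def laplacian(self) -> sp.csr_matrix:
        return laplacian(self)

    def edges(self) -> list[tuple[int, int]]:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return sorted(zip(coo.row.tolist(), coo.col.tolist()))

    def to_edge_list_frame(self) -> pd.DataFrame:
        """Edge list with (date, hour) labels for inspection/export."""
        rows = []
        for a, b in self.edges():
            rows.append((
                a, b,
                self.days[a // 24].isoformat(), a % 24,
                self.days[b // 24].isoformat(), b % 24,
            ))
        return pd.DataFrame(
            rows, columns=["node_a", "node_b", "date_a", "hour_a",
                           "date_b", "hour_b"]
        )


def build_time_graph(
    days: list[dt.date],
    hour_weight: float = 1.0,
    day_weight: float = 1.0,
) -> TimeGraph:
    """Build the spiral-with-crosslinks graph over the given day grid.

    Edges (all unit weight by default):

    * (d, h) — (d, h+1) for h = 0..22 within each day,
    * (d, 23) — (d+1, 0) and (d, h) — (d+1, h) for every h, but only when
      d+1 is the calendar day immediately after d.

    Days missing from ``days`` therefore leave the flanking runs of
    consecutive days as separate connected components. Days *listed* in the
    grid always contribute 24 nodes, even if no data were collected on them.
    """
    if len(set(days)) != len(days):
        raise ValidationError("duplicate dates in day grid")
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValidationError("day grid must be strictly increasing")

    n_days = len(days)
    n = 24 * n_days
    rows: list[int] = []
    cols: list[int] = []
    wts: list[float] = []

    def add(a: int, b: int, w: float) -> None:
        rows.extend((a, b))
        cols.extend((b, a))
        wts.extend((w, w))

    for j in range(n_days):
        base = 24 * j
        for i in range(23):
            add(base + i, base + i + 1, hour_weight)
        if j + 1 < n_days and days[j + 1] == days[j] + dt.timedelta(days=1):
            nxt = base + 24
            add(base + 23, nxt, hour_weight)       # midnight wrap
            for i in range(24):
                add(base + i, nxt + i, day_weight)  # same-hour crosslink

    adjacency = sp.csr_matrix(
        (np.array(wts), (np.array(rows), np.array(cols))), shape=(n, n)
    )
    return TimeGraph(days=list(days), adjacency=adjacency)


def laplacian(graph: TimeGraph) -> sp.csr_matrix:
    """Combinatorial Laplacian L = D - A (sparse, symmetric PSD)."""
    A = graph.adjacency
    deg = np.asarray(A.sum(axis=1)).ravel()
    return (sp.diags(deg) - A).tocsr()
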