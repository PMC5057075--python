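"""Functional-connectivity graph construction.

A subject's node x time matrix is turned into a Pearson correlation matrix and
then binarized at a fixed *link density*: the fraction of retained edges out of
all N(N-1)/2 possible node pairs.  The threshold is subject-dependent — it is
whatever absolute-correlation cut yields exactly the target edge count — so
graphs from different subjects are comparable in size.  Graphs across an
ascending density sweep are nested (same |r| ranking, larger cut).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TimeSeriesMatrix",
    "CorrelationMatrix",
    "BinaryGraph",
    "correlation_matrix",
    "target_edge_count",
    "threshold_to_density",
    "density_sweep",
    "connected_components",
]


@dataclass
class TimeSeriesMatrix:
    """One subject's node x time numeric matrix.

    ``values`` has shape (n_nodes, n_timepoints); node order is assumed to be
    the cohort-wide canonical order.
    """

    values: np.ndarray
    node_ids: list[str] | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time-series matrix must be 2-D (nodes x time)")
        if self.values.shape[1] < 3:
            raise ValueError("need at least 3 timepoints")
        if not np.isfinite(self.values).all():
            raise ValueError("time-series matrix contains non-finite values")
        if self.node_ids is None:
            self.node_ids = [str(i) for i in range(self.values.shape[0])]
        elif len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node_ids length does not match row count")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    r: np.ndarray
    method: str = "pearson"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.ndim != 2 or self.r.shape[1] != n:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-8:
            raise ValueError("correlation entries must lie in [-1, 1]")
        # enforce exact symmetry and unit diagonal
        self.r = (self.r + self.r.T) / 2.0
        np.fill_diagonal(self.r, 1.0)

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]


@dataclass(eq=False)
class BinaryGraph:
    """Undirected simple graph realized at one link density.

    ``edges`` is an (M, 2) integer array with i < j in each row, sorted
    lexicographically.  ``threshold_used`` records the |r| of the weakest
    retained edge when the graph came from a correlation matrix.
    """

    n_nodes: int
    edges: np.ndarray
    density: float
    threshold_used: float = float("nan")
    _nx_cache: nx.Graph | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if e.size and (e.min() < 0 or e.max() >= self.n_nodes):
            raise ValueError("edge endpoint out of range")
        if e.size and (e[:, 0] == e[:, 1]).any():
            raise ValueError("self-loops are not allowed")
        e = np.sort(e, axis=1)
        order = np.lexsort((e[:, 1], e[:, 0]))
        e = e[order]
        if e.shape[0] > 1 and (e[1:] == e[:-1]).all(axis=1).any():
            raise ValueError("duplicate edges are not allowed")
        self.edges = e

    @property
    def m(self) -> int:
        return self.edges.shape[0]

    def degree_vector(self) -> np.ndarray:
        """Integer degree of every node (handshake: sums to 2M)."""
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)

    def to_networkx(self) -> nx.Graph:
        if self._nx_cache is None:
            g = nx.Graph()
            g.add_nodes_from(range(self.n_nodes))
            g.add_edges_from(map(tuple, self.edges))
            self._nx_cache = g
        return self._nx_cache

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    @classmethod
    def from_networkx(cls, g: nx.Graph, density: float = float("nan")) -> "BinaryGraph":
        nodes = sorted(g.nodes())
        index = {v: k for k, v in enumerate(nodes)}
        edges = np.array([[index[u], index[v]] for u, v in g.edges()], dtype=np.int64).reshape(-1, 2)
        return cls(n_nodes=g.number_of_nodes(), edges=edges, density=density)


def correlation_matrix(ts: TimeSeriesMatrix) -> CorrelationMatrix:
    """Pearson correlation over time for all node pairs.

    Raises ``ValueError`` naming the offending nodes if any series has zero
    variance (callers may drop or jitter those nodes upstream).
    """
    sd = ts.values.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [ts.node_ids[i] for i in bad[:10]]
        raise ValueError(f"zero-variance node series: {names}" + (" ..." if bad.size > 10 else ""))
    r = np.corrcoef(ts.values)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(r=r)


def target_edge_count(n_nodes: int, density: float) -> int:
    """Edge count M = floor(density * N(N-1)/2).

    floor (never round) so the realized density never exceeds the nominal one.
    A tiny epsilon guards against binary float representation of the product
    (it never changes the exact rational floor).
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    possible = n_nodes * (n_nodes - 1) // 2
    m = math.floor(density * possible + 1e-9)
    if m < 1:
        raise ValueError(f"density {density} with N={n_nodes} yields zero edges")
    return m


def _ranked_pairs(corr: CorrelationMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Off-diagonal pairs (i<j) ranked by |r| descending, ties lexicographic."""
    n = corr.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    absr = np.abs(corr.r[iu, ju])
    order = np.lexsort((ju, iu, -absr))
    return iu[order], ju[order], absr[order]


def threshold_to_density(corr: CorrelationMatrix, density: float) -> BinaryGraph:
    """Binarize a correlation matrix at a fixed link density.

    Keeps exactly M = ``target_edge_count`` node pairs with the largest |r|
    (absolute value: strong negative correlations also create edges).  Ties at
    the cut are broken by lexicographic node-pair order, so reruns are
    bit-identical.
    """
    m = target_edge_count(corr.n_nodes, density)
    iu, ju, absr = _ranked_pairs(corr)
    if np.count_nonzero(absr) < m:
        raise ValueError(f"only {np.count_nonzero(absr)} nonzero |r| values; need {m}")
    edges = np.column_stack([iu[:m], ju[:m]])
    return BinaryGraph(
        n_nodes=corr.n_nodes,
        edges=edges,
        density=density,
        threshold_used=float(absr[m - 1]),
    )


def density_sweep(corr: CorrelationMatrix, densities: Sequence[float]) -> list[BinaryGraph]:
    """Graphs at each density, ascending; edge sets are nested by construction."""
    densities = list(densities)
    if densities != sorted(densities):
        raise ValueError("densities must be sorted ascending")
    iu, ju, absr = _ranked_pairs(corr)
    out = []
    for d in densities:
        m = target_edge_count(corr.n_nodes, d)
        if np.count_nonzero(absr) < m:
            raise ValueError(f"only {np.count_nonzero(absr)} nonzero |r| values; need {m}")
        edges = np.column_stack([iu[:m], ju[:m]])
        out.append(
            BinaryGraph(
                n_nodes=corr.n_nodes, edges=edges, density=d, threshold_used=float(absr[m - 1])
            )
        )
    return out


def connected_components(graph: BinaryGraph) -> list[set[int]]:
    """Connected components, largest first; len == 1 means fully connected."""
    comps = [set(c) for c in nx.connected_components(graph.to_networkx())]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def is_fully_connected(graph: BinaryGraph) -> bool:
    return len(connected_components(graph)) == 1
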