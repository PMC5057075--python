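"""Consensus community detection and partition comparison.

The workhorse is Louvain modularity optimization with a structural resolution
parameter gamma.  Because correlation networks exhibit modularity degeneracy
(many distinct near-optimal partitions), a consensus partition is built from
repeated runs: the co-assignment frequency matrix over repetitions is
thresholded (default 100 repetitions, threshold 0.9) and the kept pairwise
relation is closed into modules by connected components.

Partition similarity is normalized mutual information, NMI = 2 I(P1;P2) /
(H(P1) + H(P2)), ranging from 0 (independent) to 1 (identical).  The
two-parameter sweep scans (link density, gamma) and selects the cell whose
consensus partition has the highest mean NMI with its grid neighbors — a
similarity peak in parameter space.

Module-allegiance maps compare a subject's partition with a baseline: subject
modules are matched one-to-one to baseline modules by maximum overlap
(assignment problem on the confusion matrix), and each node scores 1 if its
matched label agrees with its baseline label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import normalized_mutual_info_score

from ._rng import child_seeds
from .graphs import BinaryGraph, CorrelationMatrix, threshold_to_density

__all__ = [
    "Partition",
    "ConsensusResult",
    "AllegianceMap",
    "louvain",
    "consensus_partition",
    "nmi",
    "parameter_sweep",
    "allegiance_map",
    "group_allegiance",
    "roi_allegiance_profile",
]


@dataclass
class Partition:
    """Node -> module labeling with provenance.

    Labels are canonicalized to 0..k-1 in order of first appearance, so two
    partitions that agree up to relabeling have identical canonical labels.
    """

    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        _, canonical = np.unique(labels, return_inverse=True)
        # relabel by first appearance for determinism independent of label values
        order = {}
        out = np.empty(labels.shape[0], dtype=np.int64)
        for idx, lab in enumerate(canonical):
            if lab not in order:
                order[lab] = len(order)
            out[idx] = order[lab]
        self.labels = out

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def modules(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.labels == c) for c in range(self.n_modules)]


@dataclass
class ConsensusResult:
    partition: Partition
    coassignment: np.ndarray
    n_reps: int
    threshold: float


@dataclass
class AllegianceMap:
    """Per-node binary agreement of a subject partition with a baseline."""

    values: np.ndarray
    subject_id: str = ""
    baseline_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("allegiance values must be binary")
        self.values = v.astype(np.int8)


def louvain(graph: BinaryGraph, gamma: float = 1.0, seed: int = 0) -> Partition:
    """One Louvain run at resolution gamma with a seeded node-sweep order."""
    if graph.m < 1:
        raise ValueError("Louvain requires at least one edge")
    comms = nx.community.louvain_communities(
        graph.to_networkx(), resolution=gamma, seed=seed
    )
    labels = np.empty(graph.n_nodes, dtype=np.int64)
    for c, members in enumerate(comms):
        labels[list(members)] = c
    return Partition(
        labels=labels, provenance={"gamma": gamma, "seed": seed, "density": graph.density}
    )


def consensus_partition(
    graph: BinaryGraph,
    gamma: float = 1.0,
    n_reps: int = 100,
    threshold: float = 0.9,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus over repeated Louvain runs.

    coassignment[i, j] is the fraction of repetitions in which nodes i and j
    share a module; pairs strictly above ``threshold`` are taken to be in the
    same module and the relation is closed by connected components (isolated
    nodes become singleton modules).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    n = graph.n_nodes
    co = np.zeros((n, n))
    for s in child_seeds(seed, n_reps):
        labels = louvain(graph, gamma=gamma, seed=s).labels
        co += labels[:, None] == labels[None, :]
    co /= n_reps
    np.fill_diagonal(co, 1.0)
    kept = nx.Graph()
    kept.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(co > threshold, k=1))
    kept.add_edges_from(zip(iu.tolist(), ju.tolist()))
    labels = np.empty(n, dtype=np.int64)
    for c, members in enumerate(nx.connected_components(kept)):
        labels[list(members)] = c
    partition = Partition(
        labels=labels,
        provenance={
            "gamma": gamma,
            "density": graph.density,
            "seed": "consensus",
            "n_reps": n_reps,
            "threshold": threshold,
        },
    )
    return ConsensusResult(
        partition=partition, coassignment=co, n_reps=n_reps, threshold=threshold
    )


def nmi(p1: Partition, p2: Partition) -> float:
    """Normalized mutual information 2 I/(H1+H2) between two partitions.

    Two trivial (single-module) partitions are identical, hence 1; a trivial
    versus a multi-module partition shares no information, hence 0.
    """
    if p1.n_nodes != p2.n_nodes:
        raise ValueError("partitions cover different node sets")
    return float(
        normalized_mutual_info_score(p1.labels, p2.labels, average_method="arithmetic")
    )


def parameter_sweep(
    corr: CorrelationMatrix,
    densities: Sequence[float],
    gammas: Sequence[float],
    seed: int = 0,
    n_reps: int = 100,
    threshold: float = 0.9,
) -> tuple[list[list[ConsensusResult]], tuple[int, int]]:
    """Consensus partitions over a (density, gamma) grid with peak selection.

    Each cell is scored by the mean NMI of its consensus partition with its
    4-neighborhood in the grid; the selected cell is the argmax, ties broken
    toward the lowest density, then the lowest gamma.  Returns the full grid
    (indexed [density][gamma]) and the selected (i, j).
    """
    densities, gammas = list(densities), list(gammas)
    if not densities or not gammas:
        raise ValueError("density and gamma grids must be non-empty")
    seeds = child_seeds(seed, len(densities) * len(gammas))
    grid: list[list[ConsensusResult]] = []
    k = 0
    for d in densities:
        graph = threshold_to_density(corr, d)
        row = []
        for g in gammas:
            row.append(
                consensus_partition(
                    graph, gamma=g, n_reps=n_reps, threshold=threshold, seed=seeds[k]
                )
            )
            k += 1
        grid.append(row)
    nd, ng = len(densities), len(gammas)
    best, best_score = (0, 0), -np.inf
    for i in range(nd):
        for j in range(ng):
            neighbors = [
                (i + di, j + dj)
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1))
                if 0 <= i + di < nd and 0 <= j + dj < ng
            ]
            if neighbors:
                score = float(
                    np.mean(
                        [
                            nmi(grid[i][j].partition, grid[a][b].partition)
                            for a, b in neighbors
                        ]
                    )
                )
            else:  # 1x1 grid
                score = 1.0
            if score > best_score + 1e-12:
                best, best_score = (i, j), score
    return grid, best


def _match_modules(subject: Partition, baseline: Partition) -> dict[int, int]:
    """Maximum-overlap one-to-one matching of subject to baseline modules."""
    if subject.n_nodes != baseline.n_nodes:
        raise ValueError("partitions cover different node sets")
    ns, nb = subject.n_modules, baseline.n_modules
    confusion = np.zeros((ns, nb))
    np.add.at(confusion, (subject.labels, baseline.labels), 1)
    rows, cols = linear_sum_assignment(-confusion)
    return {int(r): int(c) for r, c in zip(rows, cols)}


def allegiance_map(subject: Partition, baseline: Partition) -> AllegianceMap:
    """Binary per-node agreement with the baseline after module matching.

    A node scores 1 iff the baseline module matched to its subject module is
    the node's own baseline module; subject modules left unmatched (when the
    subject has more modules than the baseline) contribute 0.
    """
    matching = _match_modules(subject, baseline)
    matched = np.array(
        [matching.get(int(s), -1) for s in subject.labels], dtype=np.int64
    )
    values = (matched == baseline.labels).astype(np.int8)
    return AllegianceMap(values=values)


def group_allegiance(maps: Sequence[AllegianceMap]) -> np.ndarray:
    """Element-wise mean of individual allegiance maps, in [0, 1]."""
    maps = list(maps)
    if not maps:
        raise ValueError("empty list of allegiance maps")
    n = maps[0].values.shape[0]
    if any(m.values.shape[0] != n for m in maps):
        raise ValueError("allegiance maps cover different node sets")
    return np.vstack([m.values for m in maps]).mean(axis=0)


def roi_allegiance_profile(
    subjects: Sequence[Partition],
    baseline: Partition,
    roi: Sequence[int],
) -> np.ndarray:
    """Per-subject allegiance of an ROI to each baseline module.

    Row s, column m holds the fraction of ROI nodes whose matched
    subject-module label is baseline module m; rows sum to <= 1 (ROI nodes in
    unmatched subject modules contribute to none).
    """
    roi_idx = np.asarray(sorted(set(int(i) for i in roi)), dtype=int)
    if roi_idx.size == 0:
        raise ValueError("ROI is empty")
    if roi_idx.min() < 0 or roi_idx.max() >= baseline.n_nodes:
        raise ValueError("ROI node index out of range")
    out = np.zeros((len(subjects), baseline.n_modules))
    for s, part in enumerate(subjects):
        matching = _match_modules(part, baseline)
        matched = np.array(
            [matching.get(int(l), -1) for l in part.labels[roi_idx]], dtype=int
        )
        for m in range(baseline.n_modules):
            out[s, m] = float((matched == m).mean())
    return out
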