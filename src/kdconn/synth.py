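"""Synthetic cohorts with block-modular correlation structure.

Emulates the statistical structure the downstream analysis assumes: each
subject is a zero-mean multivariate Gaussian time series whose latent
correlation matrix has `r_within` inside modules and `r_between` across
them, optionally jittered per subject and re-projected to the nearest
positive-semidefinite correlation matrix.  Two planted-disruption
constructions provide a known ground truth for k_D parameter recovery:

* ``plant_disruption`` (degree-mix): d' = (1 - lam) d + lam pi(d) with pi a
  uniform random permutation; the expected regression slope of (d' - d) on d
  is exactly -lam, giving a closed-form oracle.
* ``rewire_disruption`` (edge-rewire): a fraction lam of edges, drawn
  preferentially from high-degree endpoints, is detached and reattached
  uniformly at random, eroding the degree rank order at the graph level so
  the full time-series -> graph -> k_D pipeline can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import child_seeds, rng_from
from .graphs import BinaryGraph, TimeSeriesMatrix

__all__ = [
    "ModularCovSpec",
    "DisruptionSpec",
    "block_correlation",
    "gen_modular_timeseries",
    "gen_cohort",
    "plant_disruption",
    "rewire_disruption",
    "add_white_noise",
]


@dataclass
class ModularCovSpec:
    """Latent block correlation structure of a synthetic cohort.

    Defaults mirror a resting-state-like cohort: 150 nodes in 6 modules of
    unequal size (size differences give the cohort a shared, hub-like degree
    hierarchy once graphs are thresholded at fixed density), moderately
    strong within-module coupling, weak between-module coupling, 300
    timepoints, and mild subject-level jitter of the latent correlation
    matrix.
    """

    n_nodes: int = 150
    module_sizes: list[int] = field(default_factory=lambda: [40, 35, 25, 20, 18, 12])
    r_within: float = 0.5
    r_between: float = 0.1
    n_timepoints: int = 300
    subject_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_nodes < 1 or self.n_timepoints < 3:
            raise ValueError("need n_nodes >= 1 and n_timepoints >= 3")
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module_sizes sum {sum(self.module_sizes)} != n_nodes {self.n_nodes}"
            )
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if not 0 <= self.r_within < 1:
            raise ValueError(f"r_within={self.r_within} must lie in [0, 1)")
        if not (0 <= self.r_between <= self.r_within):
            raise ValueError(
                f"r_between={self.r_between} must lie in [0, r_within={self.r_within}]"
            )
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be nonnegative")
        c = block_correlation(self)
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ValueError(
                f"block correlation (r_within={self.r_within}, "
                f"r_between={self.r_between}, sizes={self.module_sizes}) is not PSD"
            )

    @property
    def module_labels(self) -> np.ndarray:
        """Planted module id per node, in canonical node order."""
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)


def block_correlation(spec: ModularCovSpec) -> np.ndarray:
    """The implied N x N block correlation matrix (unit diagonal)."""
    labels = np.repeat(np.arange(len(spec.module_sizes)), spec.module_sizes)
    same = labels[:, None] == labels[None, :]
    c = np.where(same, spec.r_within, spec.r_between).astype(float)
    np.fill_diagonal(c, 1.0)
    return c


def _nearest_corr_psd(c: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone and restore the unit diagonal."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    w = np.clip(w, 1e-10, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def gen_modular_timeseries(
    spec: ModularCovSpec, seed: int, subject_id: str = ""
) -> TimeSeriesMatrix:
    """One subject: Gaussian sample from the (jittered) block correlation.

    Rows are z-scored.  With ``subject_noise_sd > 0`` the latent matrix is
    perturbed by symmetric Gaussian noise on the off-diagonal and projected
    back to the nearest PSD correlation matrix, so subjects share modular
    structure but differ in their exact connectivity.
    """
    rng = rng_from(seed)
    c = block_correlation(spec)
    if spec.subject_noise_sd > 0:
        jitter = rng.normal(0.0, spec.subject_noise_sd, size=c.shape)
        jitter = (jitter + jitter.T) / 2.0
        np.fill_diagonal(jitter, 0.0)
        c = _nearest_corr_psd(np.clip(c + jitter, -1.0, 1.0))
    # Cholesky with a small ridge for numerically singular matrices
    try:
        chol = np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(c + 1e-8 * np.eye(c.shape[0]))
    x = chol @ rng.standard_normal((spec.n_nodes, spec.n_timepoints))
    return TimeSeriesMatrix(values=_zscore_rows(x), subject_id=subject_id)


def gen_cohort(spec: ModularCovSpec, n_subjects: int, seed: int) -> list[TimeSeriesMatrix]:
    """Independent subject draws with per-subject derived seeds."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    seeds = child_seeds(seed, n_subjects)
    return [
        gen_modular_timeseries(spec, s, subject_id=f"sub-{i:03d}")
        for i, s in enumerate(seeds)
    ]


@dataclass
class DisruptionSpec:
    """Planted degree rank-order disruption of magnitude ``lam`` in [0, 1]."""

    lam: float
    mode: str = "degree-mix"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lam <= 1:
            raise ValueError(f"lam={self.lam} must lie in [0, 1]")
        if self.mode not in ("degree-mix", "edge-rewire"):
            raise ValueError(f"unknown disruption mode {self.mode!r}")


def plant_disruption(degrees: np.ndarray, spec: DisruptionSpec) -> np.ndarray:
    """Degree-mix disruption: d' = (1 - lam) d + lam pi(d).

    pi is a uniform random permutation of the degree vector; because pi(d) is
    uncorrelated with d in expectation, the expected slope of (d' - d)
    regressed on d equals -lam exactly.
    """
    if spec.mode != "degree-mix":
        raise ValueError("plant_disruption requires mode='degree-mix'")
    d = np.asarray(degrees, dtype=float)
    if (d < 0).any():
        raise ValueError("degrees must be nonnegative")
    if spec.lam == 0:
        return d.copy()
    rng = rng_from(spec.seed)
    return (1.0 - spec.lam) * d + spec.lam * rng.permutation(d)


def rewire_disruption(graph: BinaryGraph, lam: float, seed: int = 0) -> BinaryGraph:
    """Edge-rewire disruption: hub-preferential detachment, uniform reattachment.

    A fraction ``lam`` of the M edges is removed with probability proportional
    to the summed endpoint degrees (so hubs lose edges first) and the same
    number of edges is added uniformly at random among non-edges.  N and M are
    conserved and the graph stays simple; k_D against the original graph
    decreases with ``lam``.
    """
    if not 0 <= lam <= 1:
        raise ValueError(f"lam={lam} must lie in [0, 1]")
    if graph.m == 0:
        raise ValueError("cannot rewire a graph with no edges")
    if lam == 0:
        return BinaryGraph(
            n_nodes=graph.n_nodes,
            edges=graph.edges.copy(),
            density=graph.density,
            threshold_used=graph.threshold_used,
        )
    rng = rng_from(seed)
    n, m = graph.n_nodes, graph.m
    n_rewire = int(round(lam * m))
    deg = graph.degree_vector().astype(float)
    weights = deg[graph.edges[:, 0]] + deg[graph.edges[:, 1]]
    weights = weights / weights.sum()
    drop = rng.choice(m, size=n_rewire, replace=False, p=weights)
    keep_mask = np.ones(m, dtype=bool)
    keep_mask[drop] = False
    edge_set = {(int(i), int(j)) for i, j in graph.edges[keep_mask]}
    added = 0
    while added < n_rewire:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        pair = (int(min(i, j)), int(max(i, j)))
        if pair in edge_set:
            continue
        edge_set.add(pair)
        added += 1
    edges = np.array(sorted(edge_set), dtype=np.int64)
    return BinaryGraph(n_nodes=n, edges=edges, density=graph.density)


def add_white_noise(ts: TimeSeriesMatrix, p: float, seed: int = 0) -> TimeSeriesMatrix:
    """Convex mix of z-scored signal with unit-variance white Gaussian noise.

    Each node series becomes z((1 - p) z(signal) + p z(wgn)); p = 0 returns
    the z-scored input (Pearson correlations unchanged), p = 1 destroys all
    inter-node correlation structure.  Re-z-scoring after mixing keeps
    correlation magnitudes comparable across levels.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"noise level p={p} must lie in [0, 1]")
    z = _zscore_rows(ts.values)
    if p == 0:
        mixed = z
    else:
        rng = rng_from(seed)
        noise = _zscore_rows(rng.standard_normal(ts.values.shape))
        mixed = _zscore_rows((1.0 - p) * z + p * noise)
    return TimeSeriesMatrix(
        values=mixed, node_ids=list(ts.node_ids), subject_id=ts.subject_id
    )
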