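"""Degree rank-order disruption index k_D.

For a subject with nodal degrees d and a reference cohort with mean nodal
degrees <d_ref>, k_D is the slope of the ordinary least-squares regression

    y = k_D * x + b,   y = d - <d_ref>,   x = <d_ref>,

fitted over all N nodes.  k_D = 0 means the subject preserves the reference
degree rank order; k_D -> -1 means hubs have lost and peripheral nodes have
gained connections until the rank order is fully randomized.

Variants: k_D' drops a designated node set from the regression (degrees are
not recomputed on a pruned graph); k_D'' evaluates the regression on random
node subsets to test whether disruption is global rather than driven by
specific regions; the noise curve re-derives graphs after mixing the time
series with white Gaussian noise at increasing levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from ._rng import child_seeds, rng_from
from .graphs import TimeSeriesMatrix, correlation_matrix, threshold_to_density
from .metrics import DegreeProfile, degree
from .synth import add_white_noise

__all__ = [
    "ReferenceDegreeMap",
    "KDResult",
    "reference_degree_map",
    "kd_index",
    "group_kd",
    "kd_after_deletion",
    "kd_random_subset",
    "kd_noise_curve",
]


@dataclass
class ReferenceDegreeMap:
    """Per-node mean degree of a reference cohort at one common density."""

    mean_degree: np.ndarray
    density: float = float("nan")
    cohort_size: int = 1
    cohort_id: str = ""

    def __post_init__(self) -> None:
        self.mean_degree = np.asarray(self.mean_degree, dtype=float)
        if self.mean_degree.ndim != 1:
            raise ValueError("reference map must be a 1-D vector")
        if (self.mean_degree < 0).any():
            raise ValueError("mean degrees must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.mean_degree.shape[0]


@dataclass
class KDResult:
    """Slope k_D, intercept b, and fit correlation R of the disruption regression."""

    kd: float
    b: float
    r_fit: float
    n_nodes_used: int
    density: float = float("nan")


def reference_degree_map(cohort: Sequence[DegreeProfile], cohort_id: str = "") -> ReferenceDegreeMap:
    """Element-wise mean degree across the reference cohort."""
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty reference cohort")
    n = cohort[0].n_nodes
    densities = {p.density for p in cohort if not np.isnan(p.density)}
    if any(p.n_nodes != n for p in cohort):
        raise ValueError("reference cohort mixes node counts")
    if len(densities) > 1:
        raise ValueError(f"reference cohort mixes densities: {sorted(densities)}")
    stack = np.vstack([p.degrees for p in cohort]).astype(float)
    density = densities.pop() if densities else float("nan")
    return ReferenceDegreeMap(
        mean_degree=stack.mean(axis=0),
        density=density,
        cohort_size=len(cohort),
        cohort_id=cohort_id,
    )


def _kd_from_arrays(subject: np.ndarray, reference: np.ndarray, density: float) -> KDResult:
    x = np.asarray(reference, dtype=float)
    y = np.asarray(subject, dtype=float) - x
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("subject and reference degree vectors must match")
    if np.ptp(x) == 0:
        raise ValueError("constant reference degree map: slope undefined")
    if np.ptp(y) == 0:
        # zero (or constant) difference vector: exact slope 0, intercept = the constant
        return KDResult(kd=0.0, b=float(y[0]), r_fit=0.0, n_nodes_used=x.size, density=density)
    fit = stats.linregress(x, y)
    return KDResult(
        kd=float(fit.slope),
        b=float(fit.intercept),
        r_fit=float(fit.rvalue),
        n_nodes_used=x.size,
        density=density,
    )


def _check_match(subject: DegreeProfile, reference: ReferenceDegreeMap) -> None:
    if subject.n_nodes != reference.n_nodes:
        raise ValueError(
            f"node count mismatch: subject {subject.n_nodes} vs reference {reference.n_nodes}"
        )
    if (
        not np.isnan(subject.density)
        and not np.isnan(reference.density)
        and subject.density != reference.density
    ):
        raise ValueError(
            f"density mismatch: subject {subject.density} vs reference {reference.density}"
        )


def kd_index(subject: DegreeProfile, reference: ReferenceDegreeMap) -> KDResult:
    """k_D of one subject against the reference mean degree map."""
    _check_match(subject, reference)
    return _kd_from_arrays(subject.degrees, reference.mean_degree, reference.density)


def group_kd(cohort: Sequence[DegreeProfile], reference: ReferenceDegreeMap) -> KDResult:
    """k_D of a group, computed on the group mean degree profile."""
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    for p in cohort:
        _check_match(p, reference)
    mean_profile = np.vstack([p.degrees for p in cohort]).astype(float).mean(axis=0)
    return _kd_from_arrays(mean_profile, reference.mean_degree, reference.density)


def mean_subject_kd(cohort: Sequence[DegreeProfile], reference: ReferenceDegreeMap) -> float:
    """Alternative group summary: mean of per-subject k_D slopes."""
    return float(np.mean([kd_index(p, reference).kd for p in cohort]))


def kd_after_deletion(
    subject: DegreeProfile,
    reference: ReferenceDegreeMap,
    deleted_nodes: Iterable[int],
) -> KDResult:
    """k_D' — the regression restricted to nodes surviving deletion.

    Degrees are NOT recomputed on a pruned graph; deleted nodes are simply
    dropped from the scatter.
    """
    _check_match(subject, reference)
    deleted = np.asarray(sorted(set(int(i) for i in deleted_nodes)), dtype=int)
    if deleted.size and (deleted.min() < 0 or deleted.max() >= subject.n_nodes):
        raise ValueError("deleted node index out of range")
    keep = np.ones(subject.n_nodes, dtype=bool)
    keep[deleted] = False
    if keep.sum() == 0:
        raise ValueError("cannot delete all nodes")
    return _kd_from_arrays(
        subject.degrees[keep], reference.mean_degree[keep], reference.density
    )


def kd_random_subset(
    subject: DegreeProfile,
    reference: ReferenceDegreeMap,
    fraction: float,
    n_perm: int = 5000,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """k_D'' — k_D from random node subsets (e.g. 10% or 1% of nodes).

    Draws ``n_perm`` independent uniform subsets of round(fraction * N) nodes
    and fits k_D on each; returns all slopes plus a median/IQR summary.
    """
    _check_match(subject, reference)
    n = subject.n_nodes
    k = int(round(fraction * n))
    if k < 3:
        raise ValueError(f"subset of {k} nodes is too small (need >= 3)")
    rng = rng_from(seed)
    values = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        values[i] = _kd_from_arrays(
            subject.degrees[idx], reference.mean_degree[idx], reference.density
        ).kd
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    summary = {
        "median": float(med),
        "iqr": float(q3 - q1),
        "mean": float(values.mean()),
        "n_perm": n_perm,
        "subset_size": k,
    }
    return values, summary


def kd_noise_curve(
    ts: TimeSeriesMatrix,
    reference: ReferenceDegreeMap,
    density: float,
    levels: Sequence[float],
    seed: int = 0,
) -> list[tuple[float, KDResult]]:
    """k_D after replacing a fraction of the signal with white Gaussian noise.

    For each level p the pipeline is: mix noise -> Pearson correlation ->
    threshold to the given density -> nodal degrees -> k_D against the clean
    reference.  Level 0 is prepended as the no-noise baseline.
    """
    levels = list(levels)
    if any(not 0 <= p <= 1 for p in levels):
        raise ValueError("noise levels must lie in [0, 1]")
    if not levels or levels[0] != 0.0:
        levels = [0.0] + levels
    out = []
    seeds = child_seeds(seed, len(levels))
    for p, s in zip(levels, seeds):
        noisy = add_white_noise(ts, p, seed=s)
        graph = threshold_to_density(correlation_matrix(noisy), density)
        prof = degree(graph, subject_id=ts.subject_id)
        out.append((p, kd_index(prof, reference)))
    return out
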