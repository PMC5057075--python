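"""Consensus Louvain, NMI, parameter sweep, and module allegiance."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kdconn as k
from kdconn.community import Partition, _match_modules

from conftest import make_sbm


def confusion_nmi(a: np.ndarray, b: np.ndarray) -> float:
    """Independent NMI oracle from the label co-occurrence confusion matrix."""
    n = a.size
    pa = Counter(a.tolist())
    pb = Counter(b.tolist())
    pab = Counter(zip(a.tolist(), b.tolist()))
    h_a = -sum(c / n * math.log(c / n) for c in pa.values())
    h_b = -sum(c / n * math.log(c / n) for c in pb.values())
    mi = sum(
        c / n * math.log((c / n) / ((pa[x] / n) * (pb[y] / n)))
        for (x, y), c in pab.items()
    )
    if h_a == 0 and h_b == 0:
        return 1.0
    if h_a + h_b == 0:
        return 0.0
    return 2 * mi / (h_a + h_b)


class TestPartition:
    def test_canonical_labels_invariant_to_relabeling(self):
        p1 = Partition(labels=np.array([5, 5, 9, 9, 2]))
        p2 = Partition(labels=np.array([0, 0, 1, 1, 2]))
        assert np.array_equal(p1.labels, p2.labels)
        assert p1.n_modules == 3


class TestLouvain:
    def test_two_cliques_recovered_any_seed(self, two_cliques):
        for seed in range(10):
            part = k.louvain(two_cliques, gamma=1.0, seed=seed)
            assert part.n_modules == 2
            assert len(set(part.labels[:5])) == 1 and len(set(part.labels[5:])) == 1

    def test_sbm_recovery(self):
        """Strongly assortative planted partition is recovered almost always."""
        hits = 0
        for seed in range(40):
            g, labels = make_sbm([25] * 4, 0.5, 0.02, seed=seed)
            part = k.louvain(g, gamma=1.0, seed=seed)
            hits += k.nmi(part, Partition(labels=labels)) >= 0.9
        assert hits >= 38  # >= 95%

    def test_high_gamma_fragments_partition(self):
        g, _ = make_sbm([25] * 4, 0.5, 0.02, seed=1)
        low = [k.louvain(g, gamma=1.0, seed=s).n_modules for s in range(20)]
        high = [k.louvain(g, gamma=20.0, seed=s).n_modules for s in range(20)]
        assert np.mean(high) > np.mean(low)

    def test_quality_beats_trivial_and_random_partitions(self):
        g, _ = make_sbm([20] * 3, 0.5, 0.05, seed=2)
        rng = np.random.default_rng(0)
        for gamma in (1.0, 1.5):
            part = k.louvain(g, gamma=gamma, seed=3)
            q = k.modularity_quality(g, part.labels, gamma=gamma)
            assert q >= k.modularity_quality(g, np.zeros(60, dtype=int), gamma=gamma)
            assert q >= k.modularity_quality(g, rng.integers(0, 3, 60), gamma=gamma)

    def test_empty_graph_rejected(self):
        g = k.BinaryGraph(n_nodes=3, edges=np.empty((0, 2), dtype=int), density=0.0)
        with pytest.raises(ValueError):
            k.louvain(g)


class TestConsensus:
    def test_unambiguous_graph_matches_single_run(self, two_cliques):
        res = k.consensus_partition(two_cliques, gamma=1.0, n_reps=10, seed=0)
        single = k.louvain(two_cliques, gamma=1.0, seed=1)
        assert k.nmi(res.partition, single) == pytest.approx(1.0)
        assert np.isin(res.coassignment, (0.0, 1.0)).all()

    def test_coassignment_is_valid(self):
        g, _ = make_sbm([20] * 3, 0.4, 0.05, seed=4)
        res = k.consensus_partition(g, gamma=1.0, n_reps=25, seed=5)
        co = res.coassignment
        assert np.allclose(co, co.T)
        assert np.allclose(np.diag(co), 1.0)
        assert co.min() >= 0 and co.max() <= 1

    def test_consensus_stabilizes_sbm(self):
        """Consensus NMI with the planted labels >= the median single-run NMI."""
        g, labels = make_sbm([25] * 4, 0.5, 0.02, seed=6)
        planted = Partition(labels=labels)
        singles = [k.nmi(k.louvain(g, seed=s), planted) for s in range(20)]
        res = k.consensus_partition(g, gamma=1.0, n_reps=50, threshold=0.9, seed=7)
        assert k.nmi(res.partition, planted) >= np.median(singles) - 1e-12

    def test_partition_consistent_with_thresholded_matrix(self):
        g, _ = make_sbm([15] * 4, 0.5, 0.05, seed=8)
        res = k.consensus_partition(g, gamma=1.0, n_reps=20, threshold=0.9, seed=9)
        same = res.partition.labels[:, None] == res.partition.labels[None, :]
        # every pair above threshold must share a consensus module
        assert same[res.coassignment > 0.9].all()


class TestNMI:
    def test_identity_and_antialigned(self):
        p = Partition(labels=np.array([0, 0, 1, 1]))
        assert k.nmi(p, p) == pytest.approx(1.0)
        q = Partition(labels=np.array([0, 1, 0, 1]))
        assert k.nmi(p, q) == pytest.approx(0.0, abs=1e-12)
        assert confusion_nmi(p.labels, q.labels) == pytest.approx(0.0, abs=1e-12)

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 4, size=60)
            b = rng.integers(0, 3, size=60)
            assert k.nmi(Partition(labels=a), Partition(labels=b)) == pytest.approx(
                confusion_nmi(a, b), abs=1e-10
            )

    def test_random_partitions_near_zero(self):
        rng = np.random.default_rng(1)
        vals = [
            k.nmi(
                Partition(labels=rng.integers(0, 6, 1000)),
                Partition(labels=rng.integers(0, 6, 1000)),
            )
            for _ in range(20)
        ]
        assert np.mean(vals) < 0.05

    def test_symmetry_and_entropy_edge_cases(self):
        rng = np.random.default_rng(2)
        a = Partition(labels=rng.integers(0, 3, 50))
        b = Partition(labels=rng.integers(0, 5, 50))
        assert k.nmi(a, b) == pytest.approx(k.nmi(b, a), abs=1e-12)
        trivial = Partition(labels=np.zeros(50, dtype=int))
        assert k.nmi(trivial, trivial) == 1.0
        assert k.nmi(trivial, a) == pytest.approx(0.0, abs=1e-12)

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            k.nmi(Partition(labels=np.zeros(4, dtype=int)), Partition(labels=np.zeros(5, dtype=int)))

    @settings(derandomize=True, max_examples=100)
    @given(
        labels_a=st.lists(st.integers(0, 4), min_size=2, max_size=30),
        shift=st.integers(0, 3),
    )
    def test_label_shift_invariance_and_self_identity(self, labels_a, shift):
        a = Partition(labels=np.array(labels_a))
        shifted = Partition(labels=np.array(labels_a) + shift)
        assert k.nmi(a, shifted) == pytest.approx(1.0)
        assert k.allegiance_map(shifted, a).values.sum() == a.n_nodes


class TestParameterSweep:
    def test_single_cell_grid(self, healthy_cohort):
        corr = k.correlation_matrix(healthy_cohort[0])
        grid, (i, j) = k.parameter_sweep(corr, [0.1], [1.5], seed=0, n_reps=5)
        assert (i, j) == (0, 0) and len(grid) == 1 and len(grid[0]) == 1

    def test_recovers_planted_modules_on_standard_grid(self, default_spec, healthy_cohort):
        """Sweep over densities 10-50% x gamma 1-2 selects a cell matching the
        planted 6-module structure of the cohort mean correlation matrix."""
        mean_r = k.CorrelationMatrix(
            r=np.mean([k.correlation_matrix(t).r for t in healthy_cohort[:10]], axis=0)
        )
        grid, (i, j) = k.parameter_sweep(
            mean_r, [0.1, 0.2, 0.3, 0.4, 0.5], [1.0, 1.25, 1.5, 1.75, 2.0],
            seed=1, n_reps=10,
        )
        planted = Partition(labels=default_spec.module_labels)
        assert k.nmi(grid[i][j].partition, planted) >= 0.9


class TestAllegiance:
    def test_relabeled_identity_gives_all_ones(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=40)
        relabel = np.array([3, 0, 2, 1])
        amap = k.allegiance_map(
            Partition(labels=relabel[labels]), Partition(labels=labels)
        )
        assert amap.values.sum() == 40

    def test_one_moved_node_gives_single_zero(self):
        labels = np.repeat([0, 1, 2], 10)
        moved = labels.copy()
        moved[0] = 1
        amap = k.allegiance_map(Partition(labels=moved), Partition(labels=labels))
        assert amap.values.sum() == 29 and amap.values[0] == 0

    def test_random_subject_matches_brute_force_matching(self):
        """Mean allegiance of random partitions equals the best one-to-one
        module overlap found by exhaustive search over label bijections."""
        import itertools

        rng = np.random.default_rng(3)
        for _ in range(10):
            base = Partition(labels=rng.integers(0, 3, size=12))
            subj = Partition(labels=rng.integers(0, 3, size=12))
            amap = k.allegiance_map(subj, base)
            best = 0
            for perm in itertools.permutations(range(3)):
                mapped = np.array([perm[l] for l in subj.labels])
                best = max(best, int((mapped == base.labels).sum()))
            assert amap.values.sum() == best

    def test_group_allegiance_mean_and_bounds(self):
        ones = k.AllegianceMap(values=np.ones(5, dtype=int))
        zeros = k.AllegianceMap(values=np.zeros(5, dtype=int))
        mean = k.group_allegiance([ones, zeros])
        assert np.allclose(mean, 0.5)
        assert np.allclose(k.group_allegiance([ones]), 1.0)
        with pytest.raises(ValueError):
            k.group_allegiance([])


class TestRoiAllegianceProfile:
    def test_identity_roi_inside_one_module(self):
        labels = np.repeat([0, 1, 2], 10)
        base = Partition(labels=labels)
        prof = k.roi_allegiance_profile([Partition(labels=labels)], base, roi=range(10, 20))
        assert np.allclose(prof[0], [0, 1, 0])

    def test_rows_bounded_and_sum_le_one(self):
        rng = np.random.default_rng(4)
        base = Partition(labels=rng.integers(0, 4, 50))
        subs = [Partition(labels=rng.integers(0, 5, 50)) for _ in range(5)]
        prof = k.roi_allegiance_profile(subs, base, roi=range(15))
        assert (prof >= 0).all() and (prof <= 1).all()
        assert (prof.sum(axis=1) <= 1 + 1e-12).all()

    def test_planted_reassignment_rate_recovered(self):
        """ROI nodes moved from module A to B with probability q show up in
        the B column of the profile at rate ~= q."""
        rng = np.random.default_rng(5)
        labels = np.repeat([0, 1, 2, 3], 25)
        base = Partition(labels=labels)
        roi = np.arange(25)  # module 0
        q = 0.3
        profs = []
        for _ in range(40):
            moved = labels.copy()
            flip = rng.random(25) < q
            moved[np.flatnonzero(flip)] = 1
            profs.append(
                k.roi_allegiance_profile([Partition(labels=moved)], base, roi)[0]
            )
        mean_prof = np.mean(profs, axis=0)
        assert mean_prof[1] == pytest.approx(q, abs=0.07)
        assert mean_prof[0] == pytest.approx(1 - q, abs=0.07)

    def test_empty_roi_rejected(self):
        base = Partition(labels=np.zeros(5, dtype=int))
        with pytest.raises(ValueError):
            k.roi_allegiance_profile([base], base, roi=[])


class TestModuleMatching:
    def test_matching_reduces_to_identity_when_partitions_agree(self):
        labels = np.repeat([0, 1, 2], 5)
        m = _match_modules(Partition(labels=labels), Partition(labels=labels))
        assert m == {0: 0, 1: 1, 2: 2}
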