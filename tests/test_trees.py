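"""Bootstrap resampling, agglomerative topologies, NNLS branch-length fits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pfclust.matrix import DistanceMatrix, MatrixError, column_distances
from pfclust.trees import (
    TreeTopology,
    agglomerative_topology,
    bootstrap_rows,
    candidate_search,
    enumerate_rooted_topologies,
    fit_branch_lengths,
    top_k,
)

from conftest import make_matrix, random_canonical_matrix


def dmat(labels, square):
    return DistanceMatrix(labels=list(labels), d=np.asarray(square, dtype=float))


def random_topology(labels, rng):
    """Random binary topology by merging random node pairs (test helper)."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return TreeTopology(nodes[0])


def random_additive_distances(labels, rng):
    """Path distances of a random tree with random nonnegative lengths."""
    topo = random_topology(labels, rng)
    lengths = {
        c: float(rng.uniform(0.5, 10.0))
        for c in topo.clades
        if c != topo.leaf_set
    }
    from pfclust.trees import FittedTree

    ft = FittedTree(topology=topo, branch_lengths=lengths, sse=0.0, loglik=0.0)
    return topo, ft.path_distances()


class TestBootstrapRows:
    def test_single_row_matrix_is_fixed_point(self, rng):
        m = make_matrix([[0, 16, 100]])
        b = bootstrap_rows(m, rng)
        assert np.array_equal(b.values, m.values)

    def test_rows_are_exact_copies_and_count_preserved(self, rng):
        m = random_canonical_matrix(rng, 7, 4)
        b = bootstrap_rows(m, rng)
        assert len(b.sources) == 7
        assert b.targets == m.targets
        originals = {tuple(r) for r in m.values}
        for row in b.values:
            assert tuple(row) in originals

    def test_deterministic_under_seed(self):
        m = random_canonical_matrix(np.random.default_rng(0), 6, 3)
        b1 = bootstrap_rows(m, np.random.default_rng(42))
        b2 = bootstrap_rows(m, np.random.default_rng(42))
        assert b1 == b2


class TestAgglomerativeTopology:
    def test_two_leaves_single_cherry(self):
        d = dmat("AB", [[0, 3], [3, 0]])
        topo = agglomerative_topology(d)
        assert frozenset("AB") in topo.clades

    def test_three_leaves_unique_nearest_pair(self):
        d = dmat("ABC", [[0, 1, 10], [1, 0, 10], [10, 10, 0]])
        topo = agglomerative_topology(d)
        assert frozenset("AB") in topo.internal_clades
        assert frozenset("AC") not in topo.internal_clades

    def test_four_leaves_two_tight_pairs(self):
        # brute-force optimum over all 4-leaf shapes: the two cherries
        d = np.full((4, 4), 20.0)
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 1.0
        np.fill_diagonal(d, 0)
        topo = agglomerative_topology(dmat("ABCD", d))
        assert frozenset("AB") in topo.internal_clades
        assert frozenset("CD") in topo.internal_clades

    def test_invalid_distance_matrix_rejected(self):
        with pytest.raises(MatrixError):
            DistanceMatrix(labels=["A", "B"], d=np.array([[0, 1], [2, 0]]))
        with pytest.raises(MatrixError):
            DistanceMatrix(labels=["A", "B"], d=np.array([[0, -1], [-1, 0]]))


class TestFitBranchLengths:
    def test_additive_data_refits_exactly(self, rng):
        labels = list("ABCDEF")
        topo, d = random_additive_distances(labels, rng)
        ft = fit_branch_lengths(topo, d)
        assert ft.sse == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(ft.path_distances().d, d.d, atol=1e-8)

    def test_two_leaves_pendant_edges_sum_to_distance(self):
        topo = TreeTopology(("A", "B"))
        ft = fit_branch_lengths(topo, dmat("AB", [[0, 10], [10, 0]]))
        assert sum(ft.branch_lengths.values()) == pytest.approx(10.0)

    def test_lower_sse_means_higher_loglik(self, rng):
        labels = list("ABCDE")
        m = random_canonical_matrix(rng, 6, 5)
        d = column_distances(m)
        d = DistanceMatrix(labels=labels, d=d.d)
        fits = [
            fit_branch_lengths(random_topology(labels, rng), d) for _ in range(6)
        ]
        fits.sort(key=lambda f: f.sse)
        for a, b in zip(fits, fits[1:]):
            if b.sse > a.sse:
                assert a.loglik > b.loglik

    def test_no_negative_edges_and_beats_zero_tree(self, rng):
        labels = list("ABCDE")
        m = random_canonical_matrix(rng, 5, 5)
        d = column_distances(m)
        d = DistanceMatrix(labels=labels, d=d.d)
        ft = fit_branch_lengths(random_topology(labels, rng), d)
        assert all(v >= 0 for v in ft.branch_lengths.values())
        sse_zero = float((d.condensed**2).sum())  # all edges forced to zero
        assert ft.sse <= sse_zero + 1e-9

    def test_label_mismatch_rejected(self):
        topo = TreeTopology(("A", "B"))
        with pytest.raises(MatrixError):
            fit_branch_lengths(topo, dmat("AC", [[0, 1], [1, 0]]))

    def test_loglik_invariant_under_leaf_relabeling_and_row_permutation(self, rng):
        m = random_canonical_matrix(rng, 8, 5, square=False)
        ens = candidate_search(m, n_bootstrap=0, seed=0)
        # row permutation of the matrix
        perm = rng.permutation(len(m.sources))
        m_perm = make_matrix(
            m.values[perm], sources=[m.sources[i] for i in perm], targets=m.targets
        )
        ens_perm = candidate_search(m_perm, n_bootstrap=0, seed=0)
        assert ens.best.loglik == pytest.approx(ens_perm.best.loglik)
        # leaf relabeling
        relabel = {t: f"X{i}" for i, t in enumerate(m.targets)}
        m_rel = make_matrix(
            m.values, sources=m.sources, targets=[relabel[t] for t in m.targets]
        )
        ens_rel = candidate_search(m_rel, n_bootstrap=0, seed=0)
        assert ens.best.loglik == pytest.approx(ens_rel.best.loglik)


class TestCandidateSearch:
    def test_zero_bootstrap_reduces_to_plain_agglomeration(self, square6):
        ens = candidate_search(square6, n_bootstrap=0, seed=7)
        assert len(ens) == 1
        direct = agglomerative_topology(column_distances(square6))
        assert ens.best.topology == direct

    def test_ensemble_size_and_sort_order(self, square6):
        ens = candidate_search(square6, n_bootstrap=25, seed=7)
        assert len(ens) == 26
        logliks = [t.loglik for t in ens.trees]
        assert logliks == sorted(logliks, reverse=True)
        assert any(t.origin == 0 for t in ens.trees)  # original tree kept

    def test_bit_identical_across_runs_with_same_seed(self, square6):
        e1 = candidate_search(square6, n_bootstrap=30, seed=3)
        e2 = candidate_search(square6, n_bootstrap=30, seed=3)
        assert [t.loglik for t in e1.trees] == [t.loglik for t in e2.trees]
        assert [t.origin for t in e1.trees] == [t.origin for t in e2.trees]
        assert [t.topology for t in e1.trees] == [t.topology for t in e2.trees]

    def test_top_k_contract(self, square6):
        ens = candidate_search(square6, n_bootstrap=10, seed=1)
        assert top_k(ens, len(ens)) == ens.trees
        assert top_k(ens, 1) == [ens.trees[0]]
        with pytest.raises(MatrixError):
            top_k(ens, len(ens) + 1)

    def test_top_k_sorts_hand_set_logliks(self, square6):
        ens = candidate_search(square6, n_bootstrap=2, seed=1)
        for t, ll in zip(ens.trees, (-5.0, -3.0, -9.0)):
            t.loglik = ll
        ens.trees.sort(key=lambda t: -t.loglik)
        best2 = top_k(ens, 2)
        assert [t.loglik for t in best2] == [-3.0, -5.0]


class TestTopologyEnumeration:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 3), (4, 15), (5, 105)])
    def test_counts_all_rooted_binary_shapes(self, n, count):
        labels = [f"L{i}" for i in range(n)]
        topos = list(enumerate_rooted_topologies(labels))
        assert len(topos) == count
        assert len({t.key() for t in topos}) == count  # all distinct

    def test_exhaustive_refit_attains_optimum_on_additive_data(self, rng):
        labels = list("ABCDE")
        topo, d = random_additive_distances(labels, rng)
        best = max(
            (fit_branch_lengths(t, d) for t in enumerate_rooted_topologies(labels)),
            key=lambda f: f.loglik,
        )
        assert best.sse == pytest.approx(0.0, abs=1e-10)


@given(st.randoms(use_true_random=False))
def test_bootstrap_then_search_never_beats_exhaustive(pyrandom):
    rng = np.random.default_rng(pyrandom.randrange(2**31))
    m = random_canonical_matrix(rng, 5, 4)
    ens = candidate_search(m, n_bootstrap=10, seed=int(rng.integers(2**31)))
    d = column_distances(m)
    oracle = max(
        fit_branch_lengths(t, d).loglik
        for t in enumerate_rooted_topologies(m.targets)
    )
    assert oracle >= ens.best.loglik - 1e-9
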