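"""Cluster input profiling: mean strengths, entropy, cluster graph."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import entropy as scipy_entropy

from pfclust.matrix import MatrixError
from pfclust.profiles import (
    ClusterAssignment,
    cluster_graph,
    input_entropy,
    mean_cluster_input,
    profile_all,
)

from conftest import make_matrix

#: Published mean inputs to the postero-medial SPL cluster (0-100 scale):
#: mdSPL, CING, pIPL, MI-dmPM, pPFC, aIPL, dmPFC.
PMSPL_PRINTED_INPUTS = (50, 31.4, 24.8, 23, 8.3, 6.6, 6.3)


def two_cluster_matrix(within=100.0, between=0.0):
    labels = ["A1", "A2", "B1", "B2"]
    assign = ClusterAssignment({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
    vals = np.full((4, 4), between)
    vals[:2, :2] = within
    vals[2:, 2:] = within
    np.fill_diagonal(vals, 0.0)
    m = make_matrix(vals, sources=labels, targets=labels, canonical=False)
    return m, assign


class TestMeanClusterInput:
    def test_uniform_block_of_hundreds(self):
        m, assign = two_cluster_matrix(between=100.0)
        assert mean_cluster_input(m, assign, "A", "B") == 100.0

    def test_half_full_block(self):
        m, assign = two_cluster_matrix()
        m.data.loc["B1", "A1"] = 100.0
        m.data.loc["B1", "A2"] = 100.0
        assert mean_cluster_input(m, assign, "A", "B") == 50.0

    def test_self_cluster_on_zero_offdiagonal_block(self):
        m, assign = two_cluster_matrix(within=0.0)
        assert mean_cluster_input(m, assign, "A", "A") == 0.0

    def test_unknown_label_rejected(self):
        m, assign = two_cluster_matrix()
        with pytest.raises(MatrixError):
            mean_cluster_input(m, assign, "A", "Z")

    def test_invariant_to_area_ordering_and_linear_in_values(self, rng):
        m, assign = two_cluster_matrix(within=67.0, between=16.0)
        perm = rng.permutation(4)
        labels = [m.sources[i] for i in perm]
        m_perm = make_matrix(
            m.values[np.ix_(perm, perm)], sources=labels, targets=labels,
            canonical=False,
        )
        assert mean_cluster_input(m, assign, "A", "B") == pytest.approx(
            mean_cluster_input(m_perm, assign, "A", "B")
        )
        m_scaled = make_matrix(m.values / 2, sources=m.sources, targets=m.targets,
                               canonical=False)
        assert mean_cluster_input(m_scaled, assign, "A", "B") == pytest.approx(
            mean_cluster_input(m, assign, "A", "B") / 2
        )


class TestInputEntropy:
    def test_uniform_distribution_attains_ln_k(self):
        assert input_entropy([7.0] * 11) == pytest.approx(np.log(11), abs=1e-12)

    def test_point_mass_has_zero_entropy(self):
        assert input_entropy([0, 0, 42.0, 0]) == 0.0

    def test_printed_pmspl_inputs(self):
        # frozen from direct evaluation of -sum p ln p on the seven values
        assert input_entropy(PMSPL_PRINTED_INPUTS) == pytest.approx(
            1.7075055204199805, abs=1e-9
        )

    def test_all_zero_vector_rejected(self):
        with pytest.raises(MatrixError):
            input_entropy([0.0, 0.0])

    @given(
        st.lists(st.floats(0.0, 100.0), min_size=2, max_size=12).filter(
            lambda v: sum(v) > 1e-6
        )
    )
    def test_matches_scipy_and_stays_in_bounds(self, v):
        h = input_entropy(v)
        assert h == pytest.approx(float(scipy_entropy(np.asarray(v))), abs=1e-9)
        assert 0.0 <= h <= np.log(len(v)) + 1e-12


class TestProfileAll:
    def test_block_diagonal_gives_pure_self_input(self):
        m, assign = two_cluster_matrix()
        for p in profile_all(m, assign):
            nonzero = [k for k, v in p.mean_input.items() if v > 0]
            assert nonzero == [p.receiving]
            assert p.H == 0.0

    def test_uniform_matrix_gives_maximal_entropy(self):
        m, assign = two_cluster_matrix(within=33.0, between=33.0)
        for p in profile_all(m, assign):
            assert p.H == pytest.approx(np.log(2), abs=1e-12)

    def test_planted_fixture_profiles_match_generator_block_means(self):
        from pfclust.synthetic import PlantedSpec, generate_planted_matrix

        spec = PlantedSpec(
            clusters=[("X", 14), ("Y", 14)],
            within_mean=67.0,
            between_mean=16.0,
            asymmetry=0.0,
            seed=5,
        )
        m, assign = generate_planted_matrix(spec)
        for p in profile_all(m, assign):
            for proj, v in p.mean_input.items():
                target = 67.0 if proj == p.receiving else 16.0
                assert v == pytest.approx(target, abs=8.0)

    def test_area_level_entropy_spans_source_areas(self):
        from pfclust.profiles import area_input_profile

        m, assign = two_cluster_matrix()  # within 100, between 0
        areas = area_input_profile(m, assign, "A")
        assert areas == {"A1": 100.0, "A2": 100.0, "B1": 0.0, "B2": 0.0}
        profs = profile_all(m, assign, level="area")
        for p in profs:
            # two equal-strength member sources -> uniform over 2 inputs
            assert p.H == pytest.approx(np.log(2), abs=1e-12)

    def test_exclude_self_mode_drops_local_input(self):
        m, assign = two_cluster_matrix(within=100.0, between=16.0)
        profs = profile_all(m, assign, include_self=False)
        for p in profs:
            assert p.receiving not in p.mean_input
            assert p.H == 0.0  # single external input left

    @given(st.randoms(use_true_random=False))
    def test_merging_projecting_clusters_never_raises_entropy_over_refinement(
        self, pyrandom
    ):
        rng = np.random.default_rng(pyrandom.randrange(2**31))
        v = rng.uniform(0.1, 100.0, size=6)
        merged = np.concatenate([[v[0] + v[1]], v[2:]])
        # brute-force recomputation on both profiles
        assert input_entropy(merged) <= input_entropy(v) + 1e-12


class TestClusterGraph:
    def test_block_diagonal_leaves_only_self_loops(self):
        m, assign = two_cluster_matrix()
        g = cluster_graph(m, assign, threshold=0.0)
        assert set(zip(g.projecting, g.receiving)) == {("A", "A"), ("B", "B")}

    def test_symmetric_matrix_gives_symmetric_weights(self):
        m, assign = two_cluster_matrix(within=67.0, between=33.0)
        g = cluster_graph(m, assign)
        w = {(p, r): x for p, r, x in zip(g.projecting, g.receiving, g.weight)}
        assert w[("A", "B")] == pytest.approx(w[("B", "A")])

    def test_maximum_edge_weight_matches_strongest_planted_block_mean(self):
        from pfclust.synthetic import (
            PUBLISHED_BLOCK_MEANS,
            PlantedSpec,
            generate_planted_matrix,
        )

        strongest = max(
            v for row in PUBLISHED_BLOCK_MEANS.values() for v in row.values()
        )
        assert strongest == 50.0  # strongest published between-cluster mean input
        spec = PlantedSpec(
            clusters=[("X", 12), ("Y", 12), ("Z", 12)],
            within_mean=50.0,
            between_mean=16.0,
            block_means={"X": {"Y": 50.0}},
            asymmetry=0.0,
            seed=3,
        )
        m, assign = generate_planted_matrix(spec)
        g = cluster_graph(m, assign)
        assert g.weight.max() == pytest.approx(50.0, abs=6.0)

    def test_edges_convert_to_networkx_digraph(self):
        import networkx as nx

        m, assign = two_cluster_matrix(within=67.0, between=33.0)
        g = cluster_graph(m, assign)
        G = nx.from_pandas_edgelist(
            g, "projecting", "receiving", edge_attr="weight", create_using=nx.DiGraph
        )
        assert G.number_of_nodes() == 2 and G.number_of_edges() == 4
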