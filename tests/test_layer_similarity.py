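"""Layer similarity operations: Tanimoto, graph distances, the exponential
distance kernel, profile kernel-cosine, treatment layer, projection,
thresholding, and equal-contribution fusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssgc import layer_similarity as ls
from ssgc.network_data import AssociationMatrix, FingerprintSet, SimilarityMatrix
from conftest import make_registry, random_similarity


def fingerprints(*bit_sets):
    reg = make_registry("drug", len(bit_sets))
    return FingerprintSet(reg, tuple(frozenset(b) for b in bit_sets))


class TestTanimoto:
    @pytest.mark.parametrize(
        "bits_a, bits_b, expected",
        [
            ({1, 2, 3}, {1, 2, 3}, 1.0),
            ({1, 2}, {3, 4}, 0.0),
            ({1, 2, 3}, {2, 3, 4}, 0.5),
            (set(), {1}, 0.0),
            (set(), set(), 0.0),  # two empty fingerprints off-diagonal
        ],
    )
    def test_pairwise_values(self, bits_a, bits_b, expected):
        S = ls.tanimoto_similarity(fingerprints(bits_a, bits_b))
        assert S.values[0, 1] == pytest.approx(expected)

    def test_diagonal_forced_to_one_even_when_empty(self):
        S = ls.tanimoto_similarity(fingerprints(set(), {1, 2}))
        assert S.values[0, 0] == 1.0 and S.values[1, 1] == 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.sets(st.integers(0, 20)), min_size=2, max_size=6))
    def test_matches_set_arithmetic(self, bit_sets):
        S = ls.tanimoto_similarity(fingerprints(*bit_sets))
        for i, a in enumerate(bit_sets):
            for j, b in enumerate(bit_sets):
                if i == j:
                    continue
                expected = len(a & b) / len(a | b) if (a | b) else 0.0
                assert S.values[i, j] == pytest.approx(expected)


class TestShortestPaths:
    def _bipartite(self, edges, m, n):
        reg_d = make_registry("drug", m)
        reg_z = make_registry("disease", n)
        B = np.zeros((m, n))
        for i, j in edges:
            B[i, j] = 1.0
        return AssociationMatrix(reg_d, reg_z, B)

    def test_drugs_sharing_a_disease_are_two_hops(self):
        adj = self._bipartite([(0, 0), (1, 0)], 2, 1)
        D = ls.shortest_path_distances(adj, mode="bipartite-rows")
        assert D.values[0, 1] == 2.0

    def test_chain_distance_four(self):
        # drugA-disX-drugB-disY-drugC
        adj = self._bipartite([(0, 0), (1, 0), (1, 1), (2, 1)], 3, 2)
        D = ls.shortest_path_distances(adj, mode="bipartite-rows")
        assert D.values[0, 2] == 4.0

    def test_isolated_node_unreachable(self):
        adj = self._bipartite([(0, 0)], 2, 1)
        D = ls.shortest_path_distances(adj, mode="bipartite-rows")
        assert np.isinf(D.values[0, 1])

    def test_bipartite_row_distances_always_even(self, rng):
        B = (rng.random((6, 5)) < 0.3).astype(float)
        adj = AssociationMatrix(make_registry("drug", 6), make_registry("disease", 5), B)
        D = ls.shortest_path_distances(adj, mode="bipartite-rows")
        finite = D.values[np.isfinite(D.values)]
        assert np.all(finite % 2 == 0)

    def test_empty_graph_all_unreachable(self):
        adj = self._bipartite([], 3, 2)
        D = ls.shortest_path_distances(adj, mode="bipartite-rows")
        off = ~np.eye(3, dtype=bool)
        assert np.isinf(D.values[off]).all()


class TestPerlmanKernel:
    def _dist(self, values):
        reg = make_registry("gene", values.shape[0])
        return ls.DistanceMatrix(reg, values)

    def test_scalar_evaluations(self):
        D = self._dist(np.array([[0.0, 1.0], [1.0, 0.0]]))
        S = ls.perlman_kernel(D, ls.KernelParams(0.3, 1.0))
        assert S.values[0, 1] == pytest.approx(0.3 * np.exp(-1.0), abs=1e-7)
        assert S.values[0, 0] == 1.0  # diagonal forced to 1, not a

        D2 = self._dist(np.array([[0.0, 2.0], [2.0, 0.0]]))
        S2 = ls.perlman_kernel(D2, ls.KernelParams(0.9, 1.0))
        assert S2.values[0, 1] == pytest.approx(0.9 * np.exp(-2.0), abs=1e-7)

    def test_unreachable_maps_to_zero(self):
        D = self._dist(np.array([[0.0, np.inf], [np.inf, 0.0]]))
        S = ls.perlman_kernel(D, ls.KernelParams(0.9, 1.0))
        assert S.values[0, 1] == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.floats(0.1, 10.0),
        st.floats(0.1, 10.0),
        st.floats(0.05, 1.0),
        st.floats(0.1, 3.0),
    )
    def test_monotone_decreasing_in_distance(self, d1, d2, a, b):
        lo, hi = sorted((d1, d2))
        D = self._dist(np.array([[0.0, lo, hi], [lo, 0.0, 1.0], [hi, 1.0, 0.0]]))
        S = ls.perlman_kernel(D, ls.KernelParams(a, b))
        assert S.values[0, 1] >= S.values[0, 2]
        if lo < hi:
            assert S.values[0, 1] > S.values[0, 2]


class TestProfileKernelSimilarity:
    def _setup(self, profiles, Sg=None):
        n_ent, l = profiles.shape
        reg_e = make_registry("drug", n_ent)
        reg_g = make_registry("gene", l)
        Sg_mat = SimilarityMatrix(reg_g, np.eye(l) if Sg is None else Sg)
        prof = AssociationMatrix(reg_e, reg_g, profiles)
        return ls.profile_kernel_similarity(prof, Sg_mat)

    def test_identical_profiles_similarity_one(self):
        S = self._setup(np.array([[1.0, 1, 0], [1, 1, 0]]))
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_nested_profile_inv_sqrt2(self):
        S = self._setup(np.array([[1.0, 0], [1, 1]]))
        assert S.values[0, 1] == pytest.approx(1 / np.sqrt(2), abs=1e-7)

    def test_empty_profile_zero_off_diagonal_one_on_diagonal(self):
        S = self._setup(np.array([[0.0, 0], [1, 1]]))
        assert S.values[0, 1] == 0.0 and S.values[0, 0] == 1.0

    def test_identity_kernel_equals_plain_cosine(self, rng):
        X = (rng.random((7, 12)) < 0.4).astype(float)
        S = self._setup(X)
        norms = np.linalg.norm(X, axis=1)
        for i in range(7):
            for j in range(7):
                if i == j or norms[i] == 0 or norms[j] == 0:
                    continue
                assert S.values[i, j] == pytest.approx(
                    X[i] @ X[j] / (norms[i] * norms[j]), abs=1e-10
                )

    def test_registry_mismatch_errors(self):
        prof = AssociationMatrix(make_registry("drug", 2), make_registry("gene", 3), np.zeros((2, 3)))
        Sg = SimilarityMatrix(make_registry("gene", 3, prefix="GX"), np.eye(3))
        with pytest.raises(ValueError):
            ls.profile_kernel_similarity(prof, Sg)


class TestTreatmentSimilarity:
    def test_shared_disease_kernel_value_and_self_one(self):
        reg_d = make_registry("drug", 3)
        reg_z = make_registry("disease", 2)
        Y = AssociationMatrix(reg_d, reg_z, np.array([[1.0, 0], [1, 0], [0, 1]]))
        Sc, Sd = ls.treatment_similarity(Y, ls.KernelParams(0.9, 1.0))
        assert Sc.values[0, 0] == 1.0
        assert Sc.values[0, 1] == pytest.approx(0.9 * np.exp(-2.0), abs=1e-7)
        # disconnected bipartite components
        assert Sc.values[0, 2] == 0.0

    def test_restricted_to_entities_with_positives(self):
        reg_d = make_registry("drug", 3)
        reg_z = make_registry("disease", 2)
        Y = AssociationMatrix(reg_d, reg_z, np.array([[1.0, 0], [0, 0], [0, 1]]))
        Sc, Sd = ls.treatment_similarity(Y)
        assert Sc.registry.ids == (reg_d.ids[0], reg_d.ids[2])

    def test_no_positives_errors(self):
        Y = AssociationMatrix(make_registry("drug", 2), make_registry("disease", 2), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            ls.treatment_similarity(Y)


class TestProjection:
    def test_all_covered_is_identity(self, rng):
        reg = make_registry("drug", 5)
        S = random_similarity(rng, reg)
        ref = random_similarity(rng, reg)
        out = ls.project_to_full(S, ref, k_neighbors=3)
        np.testing.assert_allclose(out.values, S.values, atol=1e-12)

    def test_single_covered_neighbor_copies_row(self):
        full = make_registry("drug", 3)
        covered = full.subset([0, 1])
        Sp = SimilarityMatrix(covered, np.array([[1.0, 0.4], [0.4, 1.0]]))
        ref_v = np.eye(3)
        ref_v[2, 0] = ref_v[0, 2] = 1.0  # uncovered 2 fully similar to 0 only
        ref = SimilarityMatrix(make_registry("drug", 3), ref_v)
        out = ls.project_to_full(Sp, ref, k_neighbors=1)
        # entity 2 inherits entity 0's similarity to entity 1
        assert out.values[2, 1] == pytest.approx(0.4)

    def test_uncovered_with_no_reference_similarity_gets_zero_row(self):
        full = make_registry("drug", 3)
        covered = full.subset([0, 1])
        Sp = SimilarityMatrix(covered, np.array([[1.0, 0.7], [0.7, 1.0]]))
        ref = SimilarityMatrix(full, np.eye(3))
        out = ls.project_to_full(Sp, ref, k_neighbors=2)
        assert out.values[2, 0] == out.values[2, 1] == 0.0
        assert out.values[2, 2] == 1.0

    def test_covered_block_is_copied(self, rng):
        full = make_registry("drug", 6)
        covered = full.subset([0, 2, 4])
        Sp = random_similarity(rng, covered)
        ref = random_similarity(rng, full)
        out = ls.project_to_full(Sp, ref, k_neighbors=2)
        for a, i in enumerate([0, 2, 4]):
            for b, j in enumerate([0, 2, 4]):
                if i != j:
                    assert out.values[i, j] == pytest.approx(Sp.values[a, b])


class TestThreshold:
    def test_threshold_rules(self, rng):
        reg = make_registry("drug", 3)
        v = np.array([[1.0, 0.05, 0.1], [0.05, 1.0, 0.3], [0.1, 0.3, 1.0]])
        S = ls.apply_threshold(SimilarityMatrix(reg, v), 0.1)
        assert S.values[0, 1] == 0.0  # below threshold removed
        assert S.values[0, 2] == 0.1  # exactly tau kept
        assert S.values[1, 2] == 0.3
        assert np.all(np.diag(S.values) == 1.0)


class TestWeightsAndFusion:
    def test_inverse_mean_weights_match_printed_values(self):
        w = ls.weights_from_means((0.017, 0.028, 0.057))
        assert w.as_tuple() == pytest.approx((0.5248, 0.3187, 0.1565), abs=5e-4)
        w2 = ls.weights_from_means((0.006, 0.028, 0.038))
        assert w2.as_tuple() == pytest.approx((0.7288, 0.1562, 0.1151), abs=5e-4)

    def test_equal_means_give_uniform_weights(self):
        w = ls.weights_from_means((0.3, 0.3, 0.3))
        assert w.as_tuple() == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_weight_times_mean_constant(self):
        means = (0.011, 0.042, 0.09)
        w = ls.weights_from_means(means)
        prods = [wk * mk for wk, mk in zip(w.as_tuple(), means)]
        assert max(prods) == pytest.approx(min(prods))

    def test_all_zero_layer_errors(self, rng):
        reg = make_registry("drug", 3)
        S0 = SimilarityMatrix(reg, np.eye(3))
        S1 = random_similarity(rng, reg)
        with pytest.raises(ValueError):
            ls.equal_contribution_weights(S0, S1, S1)

    def test_fuse_degenerate_weights_returns_first_layer(self, rng):
        reg = make_registry("drug", 4)
        Sb, Sg, St = (random_similarity(rng, reg) for _ in range(3))
        out = ls.fuse_layers(Sb, Sg, St, ls.LayerWeights(1.0, 0.0, 0.0))
        np.testing.assert_allclose(out.values, Sb.values, atol=1e-12)

    def test_fuse_identical_matrices_fixed_point(self, rng):
        reg = make_registry("drug", 4)
        M = random_similarity(rng, reg)
        out = ls.fuse_layers(M, M, M, ls.LayerWeights(0.2, 0.5, 0.3))
        np.testing.assert_allclose(out.values, M.values, atol=1e-12)

    def test_entrywise_arithmetic(self):
        reg = make_registry("drug", 2)
        def mat(x):
            return SimilarityMatrix(reg, np.array([[1.0, x], [x, 1.0]]))
        out = ls.fuse_layers(mat(0.2), mat(0.5), mat(0.8), ls.LayerWeights(0.53, 0.32, 0.15))
        assert out.values[0, 1] == pytest.approx(0.386)

    def test_fusion_bounded_by_inputs(self, rng):
        reg = make_registry("drug", 6)
        mats = [random_similarity(rng, reg) for _ in range(3)]
        w = ls.weights_from_means((0.2, 0.3, 0.4))
        out = ls.fuse_layers(*mats, w)
        stack = np.stack([M.values for M in mats])
        assert (out.values >= stack.min(axis=0) - 1e-12).all()
        assert (out.values <= stack.max(axis=0) + 1e-12).all()

    def test_layer_weights_validation(self):
        with pytest.raises(ValueError):
            ls.LayerWeights(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            ls.LayerWeights(-0.2, 0.6, 0.6)


class TestSimilarityInvariants:
    def test_every_producer_yields_valid_similarity(self, rng):
        """Symmetry, unit diagonal, [0,1] range hold for each layer op."""
        fps = fingerprints({1, 2}, {2, 3}, set(), {0, 1, 2, 3})
        S_list = [ls.tanimoto_similarity(fps)]
        reg_g = make_registry("gene", 8)
        adj = (rng.random((8, 8)) < 0.3)
        adj = np.triu(adj, 1)
        adj = (adj | adj.T).astype(float)
        gg = AssociationMatrix(reg_g, reg_g, adj)
        D = ls.shortest_path_distances(gg, mode="unipartite")
        Sg = ls.perlman_kernel(D, ls.GENE_KERNEL)
        S_list.append(Sg)
        prof = AssociationMatrix(make_registry("drug", 4), reg_g, (rng.random((4, 8)) < 0.4).astype(float))
        S_list.append(ls.profile_kernel_similarity(prof, Sg))
        for S in S_list:
            v = S.values
            assert np.abs(v - v.T).max() <= 1e-12
            assert np.all(np.diag(v) == 1.0)
            assert v.min() >= 0.0 and v.max() <= 1.0
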