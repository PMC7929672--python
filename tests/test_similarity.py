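"""Unit and property tests for the five similarity measures."""

import numpy as np
import pytest

from dcfmda.containers import (
    AssociationMatrix,
    DiseaseDAG,
    DiseaseGeneMap,
    GeneNetwork,
    SimilarityMatrix,
    Vocabulary,
)
from dcfmda import similarity as sim

from conftest import (
    brute_force_contribution,
    brute_force_semantic_value,
    brute_force_ssd,
    chain_dag,
    random_dag,
    tiny_similarity,
)


class TestSemanticSimilarity:
    def test_single_node_dag(self):
        dag = DiseaseDAG("d", frozenset({"d"}), frozenset())
        assert sim.semantic_contribution(dag) == {"d": 1.0}
        assert sim.semantic_value(dag) == 1.0

    def test_parent_contributes_half(self):
        dag = chain_dag("d", "a")
        assert sim.semantic_contribution(dag) == {"d": 1.0, "a": 0.5}
        assert sim.semantic_value(dag) == 1.5

    def test_chain_contributions_decay(self):
        dag = chain_dag("d", "a", "r")
        assert sim.semantic_contribution(dag) == {"d": 1.0, "a": 0.5, "r": 0.25}
        assert sim.semantic_value(dag) == 1.75

    def test_diamond_takes_max_over_children(self):
        # d has parents a and b; both under root r: r's contribution is
        # max(0.5*D(a), 0.5*D(b)) = 0.25
        nodes = frozenset({"d", "a", "b", "r"})
        edges = frozenset({("a", "d"), ("b", "d"), ("r", "a"), ("r", "b")})
        contrib = sim.semantic_contribution(DiseaseDAG("d", nodes, edges))
        assert contrib == {"d": 1.0, "a": 0.5, "b": 0.5, "r": 0.25}

    def test_identical_dags_have_similarity_one(self):
        dag = chain_dag("d", "a", "r")
        assert sim.disease_semantic_similarity(dag, dag) == 1.0

    def test_shared_parent_two_chains(self):
        d1 = chain_dag("d1", "a")
        d2 = chain_dag("d2", "a")
        assert sim.disease_semantic_similarity(d1, d2) == pytest.approx(1 / 3, abs=1e-12)

    def test_disjoint_dags_have_similarity_zero(self):
        d1 = chain_dag("d1", "a")
        d2 = chain_dag("d2", "b")
        assert sim.disease_semantic_similarity(d1, d2) == 0.0

    def test_cycle_rejected_naming_node(self):
        with pytest.raises(ValueError, match="cycle"):
            DiseaseDAG("d", frozenset({"d", "a"}),
                       frozenset({("a", "d"), ("d", "a")}))

    def test_matches_brute_force_on_random_dags(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            dag = random_dag(rng)
            contrib = sim.semantic_contribution(dag)
            for node in dag.nodes:
                assert contrib[node] == brute_force_contribution(dag, node)
            assert sim.semantic_value(dag) == brute_force_semantic_value(dag)

    def test_ssd_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(43)
        for _ in range(25):
            a, b = random_dag(rng, 10), random_dag(rng, 10)
            got = sim.disease_semantic_similarity(a, b)
            assert got == brute_force_ssd(a, b)
            assert got == sim.disease_semantic_similarity(b, a)

    def test_adding_shared_ancestor_never_decreases_ssd(self):
        # attach a common root above both chains
        d1, d2 = chain_dag("d1", "a"), chain_dag("d2", "b")
        before = sim.disease_semantic_similarity(d1, d2)
        d1x = chain_dag("d1", "a", "r")
        d2x = chain_dag("d2", "b", "r")
        after = sim.disease_semantic_similarity(d1x, d2x)
        assert after >= before


@pytest.fixture()
def toy_network():
    # raw LLS 1..5; min-max puts (g1,g2) at (4-1)/(5-1)=0.75
    return GeneNetwork.from_edges([
        ("g1", "g2", 4.0),
        ("g2", "g3", 5.0),
        ("g3", "g4", 1.0),
    ])


class TestFunctionalSimilarity:
    def test_identical_gene_similarity_is_one(self, toy_network):
        assert sim.gene_pair_similarity(toy_network, "g1", "g1") == 1.0

    def test_edge_weight_is_minmax_normalised(self, toy_network):
        # independent normalisation oracle over the raw scores {4, 5, 1}
        raw = {("g1", "g2"): 4.0, ("g2", "g3"): 5.0, ("g3", "g4"): 1.0}
        lo, hi = min(raw.values()), max(raw.values())
        expect = (raw[("g1", "g2")] - lo) / (hi - lo)
        assert sim.gene_pair_similarity(toy_network, "g1", "g2") == expect
        assert sim.gene_pair_similarity(toy_network, "g2", "g3") == 1.0
        assert sim.gene_pair_similarity(toy_network, "g3", "g4") == 0.0

    def test_missing_edge_and_unknown_gene_are_zero(self, toy_network):
        assert sim.gene_pair_similarity(toy_network, "g1", "g4") == 0.0
        assert sim.gene_pair_similarity(toy_network, "g1", "nope") == 0.0

    def test_gene_to_set_takes_best_match(self, toy_network):
        assert sim.gene_to_set_association(toy_network, "g1", {"g1", "g3"}) == 1.0
        assert sim.gene_to_set_association(toy_network, "g1", {"g2", "g4"}) == 0.75
        with pytest.raises(ValueError):
            sim.gene_to_set_association(toy_network, "g1", set())

    def test_disease_similarity_identical_sets(self, toy_network):
        assert sim.disease_functional_similarity(toy_network, {"g1", "g2"},
                                                 {"g1", "g2"}) == 1.0

    def test_disease_similarity_single_gene_pair(self):
        net = GeneNetwork.from_edges([("g1", "g2", 2.0), ("g3", "g4", 0.0)])
        # (g1,g2) normalises to 1.0 here (max edge); build the 0.8 case
        net2 = GeneNetwork.from_edges(
            [("g1", "g2", 8.0), ("g3", "g4", 0.0), ("g4", "g5", 10.0)]
        )
        assert sim.disease_functional_similarity(net2, {"g1"}, {"g2"}) == \
            pytest.approx(0.8, abs=1e-12)
        assert sim.disease_functional_similarity(net, {"g1"}, {"g3"}) == 0.0

    def test_empty_gene_set_rejected(self, toy_network):
        with pytest.raises(ValueError):
            sim.disease_functional_similarity(toy_network, set(), {"g1"})

    def test_cross_edge_never_decreases_fsd(self):
        base = [("g1", "g2", 1.0), ("g9", "g8", 5.0)]
        g1, g2 = {"g1"}, {"g3"}
        before = sim.disease_functional_similarity(
            GeneNetwork.from_edges(base), g1, g2)
        after = sim.disease_functional_similarity(
            GeneNetwork.from_edges(base + [("g1", "g3", 3.0)]), g1, g2)
        assert after >= before


class TestMirnaFunctionalSimilarity:
    def _ssd(self):
        labels = ["d0", "d1", "d2", "d3", "d4", "d5"]
        vals = np.eye(6)
        vals[1, 2] = vals[2, 1] = 0.4
        vals[0, 2] = vals[2, 0] = 0.2
        vals[0, 3] = vals[3, 0] = 0.7
        return tiny_similarity(labels, vals, "SSD")

    def test_group_similarity_examples(self):
        ssd = self._ssd()
        assert sim.disease_group_similarity(ssd, "d0", ["d0", "d1"]) == 1.0
        assert sim.disease_group_similarity(ssd, "d0", ["d2", "d3"]) == 0.7
        assert sim.disease_group_similarity(ssd, "d4", ["d1", "d2"]) == 0.0
        with pytest.raises(ValueError):
            sim.disease_group_similarity(ssd, "d0", [])

    def test_identical_disease_sets_give_one(self, toy_assoc):
        ssd = tiny_similarity(toy_assoc.diseases.identifiers, np.eye(6), "SSD")
        # m1 and m3 both associate with d1 only after restricting
        a = AssociationMatrix(
            toy_assoc.mirnas, toy_assoc.diseases,
            np.array([[0, 1, 0, 0, 0, 0]] * 5),
        )
        assert sim.mirna_functional_similarity(ssd, a, "m0", "m1") == 1.0

    def test_single_disease_pair_value(self):
        ssd = self._ssd()
        vals = np.zeros((2, 6), dtype=int)
        vals[0, 1] = 1  # m0 -> d1
        vals[1, 2] = 1  # m1 -> d2
        a = AssociationMatrix(Vocabulary(["m0", "m1"]),
                              Vocabulary(self._ssd().labels), vals)
        got = sim.mirna_functional_similarity(ssd, a, "m0", "m1")
        assert got == pytest.approx(0.4, abs=1e-12)

    def test_empty_disease_set_is_nan_sentinel(self):
        ssd = self._ssd()
        vals = np.zeros((2, 6), dtype=int)
        vals[0, 1] = 1
        a = AssociationMatrix(Vocabulary(["m0", "m1"]),
                              Vocabulary(ssd.labels), vals)
        assert np.isnan(sim.mirna_functional_similarity(ssd, a, "m0", "m1"))

    def test_fsm_matrix_falls_back_to_zero_for_orphans(self):
        ssd = self._ssd()
        vals = np.zeros((3, 6), dtype=int)
        vals[0, 1] = vals[1, 1] = 1
        a = AssociationMatrix(Vocabulary(["m0", "m1", "m2"]),
                              Vocabulary(ssd.labels), vals)
        fsm = sim.functional_mirna_matrix(ssd, a)
        assert fsm.values[0, 1] == 1.0
        assert fsm.values[0, 2] == 0.0  # m2 has no diseases
        assert fsm.values[2, 2] == 0.0  # orphan diagonal left at 0


class TestGaussianKernel:
    def test_identical_profiles_score_one(self):
        profiles = np.array([[1.0, 1.0], [1.0, 1.0], [0.0, 1.0]])
        k = sim.gaussian_profile_kernel(profiles, Vocabulary("abc"), "GM")
        assert k.values[0, 1] == 1.0

    def test_orthogonal_unit_profiles(self):
        profiles = np.array([[1.0, 0.0], [0.0, 1.0]])
        k = sim.gaussian_profile_kernel(profiles, Vocabulary("ab"), "GM", 1.0)
        # mean squared norm 1, bandwidth 1, squared distance 2
        assert k.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-9)

    def test_all_zero_profiles_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            sim.gaussian_profile_kernel(np.zeros((3, 4)), Vocabulary("abc"), "GD")

    def test_joint_coordinate_permutation_invariance(self):
        rng = np.random.default_rng(5)
        profiles = (rng.random((6, 8)) < 0.3).astype(float)
        profiles[0, 0] = 1.0  # ensure nonzero
        perm = rng.permutation(8)
        k1 = sim.gaussian_profile_kernel(profiles, Vocabulary("abcdef"), "GM")
        k2 = sim.gaussian_profile_kernel(profiles[:, perm], Vocabulary("abcdef"), "GM")
        np.testing.assert_allclose(k1.values, k2.values, atol=1e-12)

    def test_kernel_orientation_matches_association_axes(self, toy_assoc):
        gm = sim.gip_mirna_kernel(toy_assoc)
        gd = sim.gip_disease_kernel(toy_assoc)
        assert gm.values.shape == (5, 5)
        assert gd.values.shape == (6, 6)


class TestIntegration:
    def test_mirna_integration_prefers_functional(self):
        labels = ["a", "b"]
        fsm = tiny_similarity(labels, [[1, 0.4], [0.4, 1]], "FSM")
        gm = tiny_similarity(labels, [[1, 0.9], [0.9, 1]], "GM")
        ism = sim.integrate_mirna_similarity(fsm, gm)
        assert ism.values[0, 1] == 0.4

    def test_mirna_integration_falls_back_to_kernel(self):
        labels = ["a", "b"]
        fsm = tiny_similarity(labels, [[1, 0.0], [0.0, 1]], "FSM")
        gm = tiny_similarity(labels, [[1, 0.9], [0.9, 1]], "GM")
        ism = sim.integrate_mirna_similarity(fsm, gm)
        assert ism.values[0, 1] == 0.9
        assert ism.values[0, 0] == 1.0

    def test_disease_integration_literal_average(self):
        labels = ["a", "b"]
        fsd = tiny_similarity(labels, [[1, 0.8], [0.8, 1]], "FSD")
        ssd = tiny_similarity(labels, [[1, 0.4], [0.4, 1]], "SSD")
        gd = tiny_similarity(labels, [[1, 0.3], [0.3, 1]], "GD")
        isd = sim.integrate_disease_similarity(fsd, ssd, gd)
        assert isd.values[0, 1] == pytest.approx(0.6, abs=1e-12)

    def test_disease_integration_halves_single_term(self):
        # the literal rule averages in the zero term
        labels = ["a", "b"]
        fsd = tiny_similarity(labels, [[1, 0.8], [0.8, 1]], "FSD")
        ssd = tiny_similarity(labels, [[1, 0.0], [0.0, 1]], "SSD")
        gd = tiny_similarity(labels, [[1, 0.3], [0.3, 1]], "GD")
        isd = sim.integrate_disease_similarity(fsd, ssd, gd)
        assert isd.values[0, 1] == pytest.approx(0.4, abs=1e-12)
        relaxed = sim.integrate_disease_similarity(fsd, ssd, gd, nonzero_mean=True)
        assert relaxed.values[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_disease_integration_kernel_fallback(self):
        labels = ["a", "b"]
        fsd = tiny_similarity(labels, [[0, 0.0], [0.0, 0]], "FSD")
        ssd = tiny_similarity(labels, [[0, 0.0], [0.0, 0]], "SSD")
        gd = tiny_similarity(labels, [[1, 0.3], [0.3, 1]], "GD")
        isd = sim.integrate_disease_similarity(fsd, ssd, gd)
        assert isd.values[0, 1] == pytest.approx(0.3, abs=1e-12)

    def test_label_mismatch_rejected(self):
        fsm = tiny_similarity(["a", "b"], np.eye(2), "FSM")
        gm = tiny_similarity(["a", "c"], np.eye(2), "GM")
        with pytest.raises(ValueError, match="label"):
            sim.integrate_mirna_similarity(fsm, gm)

    def test_integration_is_idempotent(self, small_bundle):
        b = small_bundle
        again = sim.integrate_mirna_similarity(b.fsm, b.gm)
        np.testing.assert_array_equal(again.values, b.ism.values)
        again_d = sim.integrate_disease_similarity(b.fsd, b.ssd, b.gd)
        np.testing.assert_array_equal(again_d.values, b.isd.values)


class TestKernelProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.integers(min_value=0, max_value=2**32 - 1),
           st.integers(min_value=2, max_value=8),
           st.integers(min_value=2, max_value=10))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_kernel_symmetric_unit_diagonal_bounded(self, seed, n, width):
        rng = np.random.default_rng(seed)
        profiles = (rng.random((n, width)) < 0.4).astype(float)
        profiles[0, 0] = 1.0  # at least one association keeps beta defined
        k = sim.gaussian_profile_kernel(
            profiles, Vocabulary(f"e{i}" for i in range(n)), "GM"
        )
        np.testing.assert_allclose(k.values, k.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(k.values), 1.0, atol=1e-12)
        assert k.values.min() > 0.0 and k.values.max() <= 1.0


class TestBundleProperties:
    def test_all_matrices_symmetric_bounded(self, small_bundle):
        for name in ("ssd", "fsd", "fsm", "gd", "gm", "ism", "isd"):
            mat = getattr(small_bundle, name).values
            np.testing.assert_allclose(mat, mat.T, atol=1e-9)
            assert mat.min() >= 0.0 and mat.max() <= 1.0

    def test_kernel_and_ism_diagonals_are_one(self, small_bundle):
        for name in ("gd", "gm", "ism"):
            np.testing.assert_allclose(
                np.diag(getattr(small_bundle, name).values), 1.0, atol=1e-12
            )

    def test_reintegrate_recomputes_kernels_only(self, small_world, small_bundle):
        masked = small_world.assoc.mask_pairs(
            small_world.assoc.positive_pairs()[:5]
        )
        redone = small_bundle.reintegrate(masked)
        assert redone.fsm is small_bundle.fsm
        assert not np.array_equal(redone.gm.values, small_bundle.gm.values)
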