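import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from katzsp import (
    AssociationMatrix,
    DiseaseOntology,
    disease_semantic_similarity,
    gip_similarity,
    integrate_similarity,
    integrated_similarities,
    lncrna_functional_similarity,
    semantic_contributions,
)
from katzsp.similarity import SimilarityMatrix


def _assoc(values):
    values = np.asarray(values, dtype=float)
    nl, nd = values.shape
    return AssociationMatrix(values, [f"l{i}" for i in range(nl)], [f"d{j}" for j in range(nd)])


binary_matrices = arrays(
    np.int8,
    st.tuples(st.integers(2, 6), st.integers(2, 6)),
    elements=st.integers(0, 1),
).filter(lambda a: a.any())


class TestSemanticContributions:
    def test_isolated_node_contributes_only_itself(self):
        dag = DiseaseOntology(node_ids={"d1"})
        sc = semantic_contributions(dag, "d1", 0.5)
        assert sc.contributions == {"d1": 1.0}

    def test_chain_one_step(self):
        dag = DiseaseOntology(edges={("d1", "d2")})
        sc = semantic_contributions(dag, "d2", 0.5)
        assert sc.contributions == {"d2": 1.0, "d1": 0.5}

    def test_chain_two_steps_and_max_over_paths(self):
        chain = DiseaseOntology(edges={("d1", "d2"), ("d2", "d3")})
        sc = semantic_contributions(chain, "d3", 0.5)
        assert sc.contributions == {"d3": 1.0, "d2": 0.5, "d1": 0.25}
        # a direct edge d1 -> d3 opens a shorter path; the max rule wins
        multi = DiseaseOntology(edges={("d1", "d2"), ("d2", "d3"), ("d1", "d3")})
        sc2 = semantic_contributions(multi, "d3", 0.5)
        assert sc2.contributions["d1"] == 0.5

    def test_absent_disease_raises(self):
        dag = DiseaseOntology(edges={("d1", "d2")})
        with pytest.raises(KeyError):
            semantic_contributions(dag, "dX", 0.5)

    @pytest.mark.parametrize("decay", [0.2, 0.5, 0.8])
    def test_strict_ancestors_bounded_by_decay(self, decay):
        dag = DiseaseOntology(edges={("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")})
        sc = semantic_contributions(dag, "d", decay)
        for node, value in sc.contributions.items():
            if node != "d":
                assert 0.0 < value <= decay


class TestDiseaseSemanticSimilarity:
    def test_diagonal_is_one_for_known_diseases(self):
        dag = DiseaseOntology(edges={("d1", "d2")})
        dd = disease_semantic_similarity(dag, ["d1", "d2"], 0.5)
        np.testing.assert_allclose(np.diag(dd.values), 1.0)

    def test_parent_child_value(self):
        dag = DiseaseOntology(edges={("d1", "d2")})
        dd = disease_semantic_similarity(dag, ["d1", "d2"], 0.5)
        assert dd.values[0, 1] == pytest.approx(0.6, abs=1e-15)

    def test_disjoint_components_are_zero(self):
        dag = DiseaseOntology(edges={("d1", "d2"), ("d3", "d4")})
        dd = disease_semantic_similarity(dag, ["d2", "d4"], 0.5)
        assert dd.values[0, 1] == 0.0

    def test_missing_disease_row_is_all_zero(self):
        dag = DiseaseOntology(edges={("d1", "d2")})
        dd = disease_semantic_similarity(dag, ["d1", "dX"], 0.5)
        assert (dd.values[1, :] == 0.0).all() and (dd.values[:, 1] == 0.0).all()

    def test_symmetric_and_bounded(self):
        dag = DiseaseOntology(edges={("a", "b"), ("a", "c"), ("b", "d"), ("c", "d"), ("b", "e")})
        dd = disease_semantic_similarity(dag, list("abcde"), 0.5)
        np.testing.assert_allclose(dd.values, dd.values.T, atol=1e-12)
        assert dd.values.min() >= 0.0 and dd.values.max() <= 1.0


class TestFunctionalSimilarity:
    def _dd(self):
        dag = DiseaseOntology(edges={("d0", "d1")})
        return disease_semantic_similarity(dag, ["d0", "d1"], 0.5)

    def test_identical_singleton_sets_give_one(self):
        ld = _assoc([[1, 0], [1, 0]])
        ll = lncrna_functional_similarity(ld, self._dd())
        assert ll.values[0, 1] == pytest.approx(1.0)

    def test_singleton_pair_matches_disease_similarity(self):
        ld = _assoc([[1, 0], [0, 1]])
        ll = lncrna_functional_similarity(ld, self._dd())
        assert ll.values[0, 1] == pytest.approx(0.6, abs=1e-15)

    def test_empty_disease_set_gives_zero_off_diagonal(self):
        ld = _assoc([[0, 0], [1, 1]])
        ll = lncrna_functional_similarity(ld, self._dd())
        assert ll.values[0, 1] == 0.0
        assert ll.values[0, 0] == 1.0  # diagonal forced to 1 even for empty sets

    def test_symmetric_and_bounded_random(self):
        rng = np.random.default_rng(5)
        ld = _assoc((rng.random((7, 5)) < 0.4).astype(float))
        dag = DiseaseOntology(edges={("d0", "d1"), ("d0", "d2"), ("d1", "d3"), ("d2", "d4")})
        dd = disease_semantic_similarity(dag, ld.disease_ids, 0.5)
        ll = lncrna_functional_similarity(ld, dd)
        np.testing.assert_allclose(ll.values, ll.values.T, atol=1e-12)
        assert ll.values.min() >= 0.0 and ll.values.max() <= 1.0


class TestGipSimilarity:
    def test_identical_profiles_give_one(self):
        ld = _assoc([[1, 0, 1], [1, 0, 1]])
        g = gip_similarity(ld, "lncrna")
        assert g.values[0, 1] == pytest.approx(1.0)

    def test_unit_norm_columns_give_unit_bandwidth(self):
        ld = _assoc([[1, 0], [0, 1]])
        g = gip_similarity(ld, "disease")
        # gamma = 1, squared distance 2 between the two columns
        assert g.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-15)

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="bandwidth undefined"):
            gip_similarity(_assoc(np.zeros((2, 2))), "disease")

    @settings(max_examples=40, deadline=None)
    @given(binary_matrices)
    def test_symmetric_bounded_unit_diagonal(self, values):
        g = gip_similarity(_assoc(values), "lncrna")
        np.testing.assert_allclose(g.values, g.values.T, atol=1e-12)
        assert g.values.min() > 0.0 and g.values.max() <= 1.0
        np.testing.assert_allclose(np.diag(g.values), 1.0)

    @settings(max_examples=25, deadline=None)
    @given(binary_matrices, st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, values, rnd):
        ld = _assoc(values)
        nl, nd = values.shape
        perm_l = list(range(nl))
        perm_d = list(range(nd))
        rnd.shuffle(perm_l)
        rnd.shuffle(perm_d)
        permuted = _assoc(values[np.ix_(perm_l, perm_d)])
        g = gip_similarity(ld, "lncrna").values
        gp = gip_similarity(permuted, "lncrna").values
        np.testing.assert_allclose(gp, g[np.ix_(perm_l, perm_l)], atol=1e-12)

    def test_sharing_an_association_never_decreases_similarity(self):
        # making two profiles agree on one more coordinate shrinks the distance
        base = np.array([[1, 0, 0, 1], [0, 1, 0, 1], [0, 0, 1, 0]], dtype=float)
        before = gip_similarity(_assoc(base), "lncrna").values[0, 1]
        shared = base.copy()
        shared[0, 1] = 1.0  # lncRNA 0 now also has lncRNA 1's disease
        after = gip_similarity(_assoc(shared), "lncrna").values[0, 1]
        # distance shrinks by 1 but the bandwidth also changes; recompute at
        # fixed bandwidth to isolate the monotone effect
        d_before = ((base[0] - base[1]) ** 2).sum()
        d_after = ((shared[0] - shared[1]) ** 2).sum()
        assert d_after <= d_before
        assert after == pytest.approx(np.exp(-gip_gamma(shared) * d_after))


def gip_gamma(values):
    return 1.0 / (values**2).sum(axis=1).mean()


class TestIntegration:
    def _pair(self, base_values, gip_values, n=2):
        ids = [f"d{j}" for j in range(n)]
        base = SimilarityMatrix(base_values, ids, "disease_semantic")
        gip = SimilarityMatrix(gip_values, ids, "disease_gip")
        return base, gip

    def test_base_nonzero_everywhere_returns_base(self):
        base, gip = self._pair(np.array([[1.0, 0.6], [0.6, 1.0]]), np.full((2, 2), 1.0) - 0.5 * (1 - np.eye(2)))
        out = integrate_similarity(base, gip)
        np.testing.assert_array_equal(out.values, base.values)

    def test_base_zero_everywhere_returns_gip(self):
        gip_values = np.array([[1.0, 0.2], [0.2, 1.0]])
        base, gip = self._pair(np.zeros((2, 2)), gip_values)
        out = integrate_similarity(base, gip)
        np.testing.assert_array_equal(out.values, gip_values)

    def test_branchwise_selection(self):
        base_values = np.array([[1.0, 0.6, 0.0], [0.6, 1.0, 0.0], [0.0, 0.0, 0.0]])
        gip_values = np.array([[1.0, 0.135, 0.2], [0.135, 1.0, 0.3], [0.2, 0.3, 1.0]])
        ids = ["d1", "d2", "d3"]
        out = integrate_similarity(
            SimilarityMatrix(base_values, ids, "disease_semantic"),
            SimilarityMatrix(gip_values, ids, "disease_gip"),
        )
        assert out.values[0, 1] == 0.6  # base wins where nonzero
        assert out.values[0, 2] == 0.2  # GIP fallback where base is zero
        assert out.values[2, 2] == 1.0  # missing disease regains a unit diagonal

    def test_id_mismatch_errors(self):
        base = SimilarityMatrix(np.eye(2), ["d1", "d2"], "disease_semantic")
        gip = SimilarityMatrix(np.eye(2), ["d1", "dX"], "disease_gip")
        with pytest.raises(ValueError, match="identical entity sets"):
            integrate_similarity(base, gip)


class TestIntegratedSimilarities:
    def test_full_stack_shapes_and_invariants(self, toy_dataset):
        ld, dag = toy_dataset
        ll_f, dd_f, dd_sem = integrated_similarities(ld, dag)
        assert ll_f.kind == "lncrna_final" and dd_f.kind == "disease_final"
        assert ll_f.n == ld.nl and dd_f.n == ld.nd
        np.testing.assert_allclose(np.diag(ll_f.values), 1.0)
        np.testing.assert_allclose(np.diag(dd_f.values), 1.0)
        # integration equals the semantic layer wherever it is nonzero
        mask = dd_sem.values != 0.0
        np.testing.assert_array_equal(dd_f.values[mask], dd_sem.values[mask])
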