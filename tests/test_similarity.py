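import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from daecfr import (
    AssociationMatrix,
    Catalog,
    SimilarityMatrix,
    TreeNumberMap,
    build_dag_forest,
    gip_kernel,
    integrate,
    logistic_transform,
    mean_semantic,
    semantic_contribution_m1,
    semantic_contribution_m2,
    semantic_similarity_m1,
    semantic_similarity_m2,
)
from daecfr.similarity import DEFAULT_OFFSET

from .conftest import random_toy_forest
from .oracles import semantic_matrix_oracle


def _assoc(values):
    values = np.asarray(values, dtype=np.int8)
    return AssociationMatrix(
        values,
        Catalog([f"m{i}" for i in range(values.shape[0])]),
        Catalog([f"d{j}" for j in range(values.shape[1])]),
    )


class TestGipKernel:
    def test_identity_closed_form(self, toy_assoc):
        K = gip_kernel(toy_assoc, "mirna")
        # mean squared profile norm is 1, squared distance between rows is 2
        assert K.values[0, 1] == pytest.approx(math.exp(-2), abs=1e-12)
        assert K.values[0, 0] == 1.0 and K.values[1, 1] == 1.0

    def test_disease_axis_uses_transpose(self):
        A = _assoc([[1, 0, 0], [1, 0, 0]])
        K = gip_kernel(A, "disease")
        assert len(K) == 3 and K.kind == "KD"
        assert K.values[1, 2] == 1.0  # identical (all-zero) columns

    def test_identical_rows_similarity_one(self):
        K = gip_kernel(_assoc([[1, 0], [1, 0], [0, 1]]), "mirna")
        assert K.values[0, 1] == pytest.approx(1.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            gip_kernel(_assoc(np.zeros((2, 2))), "mirna")

    def test_gamma_prime_scales_bandwidth(self, toy_assoc):
        K1 = gip_kernel(toy_assoc, "mirna", gamma_prime=1.0)
        K2 = gip_kernel(toy_assoc, "mirna", gamma_prime=2.0)
        assert K2.values[0, 1] == pytest.approx(K1.values[0, 1] ** 2)

    @given(st.integers(0, 2**30))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_range_property(self, seed):
        rng = np.random.default_rng(seed)
        values = (rng.random((rng.integers(2, 7), rng.integers(2, 7))) < 0.4)
        if values.sum() == 0:
            values.flat[0] = True
        K = gip_kernel(_assoc(values.astype(np.int8)), "mirna")
        assert np.array_equal(K.values, K.values.T)
        assert np.all(np.diag(K.values) == 1.0)
        assert K.values.min() >= 0 and K.values.max() <= 1


class TestDagForest:
    def test_prefix_chain(self):
        catalog = Catalog(["d1"])
        forest = build_dag_forest(TreeNumberMap({"d1": {"C14.280.647"}}), catalog)
        assert forest.nodes["d1"] == {"C14", "C14.280", "d1"}
        assert ("C14.280", "C14") in forest.edges["d1"]
        assert ("d1", "C14.280") in forest.edges["d1"]

    def test_multiple_tree_numbers_union(self):
        forest = build_dag_forest(
            TreeNumberMap({"d1": {"C14.280", "C16.131"}}), Catalog(["d1"])
        )
        assert forest.nodes["d1"] == {"C14", "C16", "d1"}

    def test_shared_prefix_dag_count(self):
        forest = build_dag_forest(
            TreeNumberMap({"d1": {"C14.280"}, "d2": {"C14.400"}}), Catalog(["d1", "d2"])
        )
        assert forest.dag_count["C14"] == 2
        assert forest.dag_count["d1"] == 1

    def test_prefix_resolves_to_owner_disease(self):
        # d2's tree number is a prefix of d1's, so d1's ancestor is d2 itself
        forest = build_dag_forest(
            TreeNumberMap({"d1": {"C14.280.647"}, "d2": {"C14.280"}}),
            Catalog(["d1", "d2"]),
        )
        assert "d2" in forest.nodes["d1"]
        assert "C14.280" not in forest.nodes["d1"]

    def test_missing_disease_empty_dag(self):
        forest = build_dag_forest(TreeNumberMap(), Catalog(["d1"]))
        assert forest.is_empty("d1")


class TestSemanticContributions:
    def _forest(self, entries, ids):
        return build_dag_forest(TreeNumberMap(entries), Catalog(ids))

    def test_chain_decay(self):
        forest = self._forest({"d1": {"P.A"}}, ["d1"])
        contrib = semantic_contribution_m1(forest, "d1")
        assert contrib == {"d1": 1.0, "P": 0.5}

    def test_two_step_decay(self):
        forest = self._forest({"d1": {"G.P.A"}}, ["d1"])
        contrib = semantic_contribution_m1(forest, "d1")
        assert contrib["G"] == pytest.approx(0.25)

    def test_multi_path_takes_max(self):
        forest = self._forest({"d1": {"X.Y.Z1", "X.Z1"}}, ["d1"])
        contrib = semantic_contribution_m1(forest, "d1")
        assert contrib["X"] == pytest.approx(0.5)

    def test_empty_dag_errors(self):
        forest = self._forest({}, ["d1"])
        with pytest.raises(ValueError, match="empty DAG"):
            semantic_contribution_m1(forest, "d1")

    def test_information_content_values(self):
        entries = {"d1": {"P.A"}, "d2": {"P.B"}, "d3": {"P.C"}, "d4": {"Q.Z"}}
        forest = self._forest(entries, ["d1", "d2", "d3", "d4"])
        contrib = semantic_contribution_m2(forest, "d1")
        assert contrib["d1"] == pytest.approx(-math.log(1 / 4), abs=1e-12)
        assert contrib["P"] == pytest.approx(-math.log(3 / 4), abs=1e-12)

    def test_node_in_all_dags_contributes_zero(self):
        forest = self._forest({"d1": {"P.A"}, "d2": {"P.B"}}, ["d1", "d2"])
        assert semantic_contribution_m2(forest, "d1")["P"] == 0.0


class TestSemanticSimilarity:
    def test_shared_parent_one_third(self):
        forest = build_dag_forest(
            TreeNumberMap({"d1": {"P.A"}, "d2": {"P.B"}}), Catalog(["d1", "d2"])
        )
        sd1 = semantic_similarity_m1(forest)
        assert sd1.values[0, 1] == pytest.approx(1 / 3, abs=1e-12)

    def test_disjoint_zero(self):
        forest = build_dag_forest(
            TreeNumberMap({"d1": {"A.B"}, "d2": {"C.D"}}), Catalog(["d1", "d2"])
        )
        assert semantic_similarity_m1(forest).values[0, 1] == 0.0
        assert semantic_similarity_m2(forest).values[0, 1] == 0.0

    def test_self_similarity_one(self):
        forest = build_dag_forest(
            TreeNumberMap({"d1": {"A.B"}}), Catalog(["d1", "d2"])
        )
        assert np.all(np.diag(semantic_similarity_m1(forest).values) == 1.0)
        assert np.all(np.diag(semantic_similarity_m2(forest).values) == 1.0)

    def test_sd2_worked_example(self):
        entries = {"d1": {"P.A"}, "d2": {"P.B"}, "d3": {"P.C"}, "d4": {"Q.Z"}}
        forest = build_dag_forest(TreeNumberMap(entries), Catalog(list(entries)))
        sd2 = semantic_similarity_m2(forest)
        p, leaf = math.log(4 / 3), math.log(4)
        assert sd2.values[0, 1] == pytest.approx(2 * p / (2 * (p + leaf)), abs=1e-12)

    @pytest.mark.parametrize("model", ["m1", "m2"])
    def test_matches_brute_force_oracle(self, model):
        compute = semantic_similarity_m1 if model == "m1" else semantic_similarity_m2
        rng = np.random.default_rng(12345)
        for _ in range(60):
            catalog, tree_map = random_toy_forest(rng)
            forest = build_dag_forest(tree_map, catalog)
            got = compute(forest).values
            expected = semantic_matrix_oracle(tree_map, catalog, model)
            np.testing.assert_allclose(got, expected, atol=1e-12)


class TestMeanAndIntegrate:
    def _sim(self, values, ids, kind):
        return SimilarityMatrix(np.asarray(values, float), Catalog(ids), kind=kind)

    def test_mean_semantic(self):
        sd1 = self._sim([[1, 1 / 3], [1 / 3, 1]], ["d1", "d2"], "SD1")
        sd2 = self._sim([[1, 0.1719], [0.1719, 1]], ["d1", "d2"], "SD2")
        ss = mean_semantic(sd1, sd2)
        assert ss.values[0, 1] == pytest.approx((1 / 3 + 0.1719) / 2)

    def test_mean_catalog_mismatch(self):
        sd1 = self._sim([[1.0]], ["d1"], "SD1")
        sd2 = self._sim([[1.0]], ["dX"], "SD2")
        with pytest.raises(ValueError, match="catalog"):
            mean_semantic(sd1, sd2)

    def test_integrate_blend_and_fallback(self):
        K = self._sim([[1, 0.8], [0.8, 1]], ["m1", "m2"], "KM")
        S = self._sim([[1, 0.4], [0.4, 1]], ["m1", "m2"], "FM")
        assert integrate(K, S).values[0, 1] == pytest.approx(0.6)
        Z = self._sim([[1, 0], [0, 1]], ["m1", "m2"], "FM")
        assert integrate(K, Z).values[0, 1] == pytest.approx(0.8)

    def test_integrate_diagonal_stays_one(self):
        K = self._sim([[1, 0.8], [0.8, 1]], ["m1", "m2"], "KM")
        S = self._sim([[1, 0.4], [0.4, 1]], ["m1", "m2"], "FM")
        assert np.all(np.diag(integrate(K, S).values) == 1.0)

    def test_integrate_requires_kernel(self):
        S = self._sim([[1, 0.4], [0.4, 1]], ["m1", "m2"], "FM")
        with pytest.raises(ValueError, match="GIP kernel"):
            integrate(S, S)

    @given(st.integers(0, 2**30))
    @settings(max_examples=25, deadline=None)
    def test_zero_entries_pass_kernel_through(self, seed):
        rng = np.random.default_rng(seed)
        n = 4
        k = rng.random((n, n))
        k = 0.5 * (k + k.T)
        np.fill_diagonal(k, 1.0)
        s = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
        s = 0.5 * (s + s.T)
        np.fill_diagonal(s, 1.0)
        ids = [f"m{i}" for i in range(n)]
        out = integrate(self._sim(k, ids, "KM"), self._sim(s, ids, "FM"))
        mask = s == 0
        np.testing.assert_array_equal(out.values[mask], k[mask])


class TestLogisticTransform:
    def _sim(self, values):
        values = np.asarray(values, float)
        ids = [f"m{i}" for i in range(len(values))]
        return SimilarityMatrix(values, Catalog(ids), kind="SM")

    def test_zero_maps_to_floor(self):
        S = self._sim([[1, 0], [0, 1]])
        out = logistic_transform(S, c=-8)
        assert out.values[0, 1] == pytest.approx(1e-4, rel=1e-12)

    def test_one_closed_form(self):
        S = self._sim([[1, 1], [1, 1]])
        out = logistic_transform(S, c=-8)
        expected = 1 / (1 + 9999 * math.exp(-8))
        assert out.values[0, 1] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.2297, abs=5e-5)

    def test_half_closed_form(self):
        S = self._sim([[1, 0.5], [0.5, 1]])
        out = logistic_transform(S, c=-8)
        assert out.values[0, 1] == pytest.approx(1 / (1 + 9999 * math.exp(-4)), rel=1e-12)
        assert out.values[0, 1] == pytest.approx(0.00543, abs=5e-6)

    def test_nonnegative_c_rejected(self):
        with pytest.raises(ValueError, match="c < 0"):
            logistic_transform(self._sim([[1.0]]), c=0.0)

    @given(st.floats(-15, -1), st.integers(0, 2**30))
    @settings(max_examples=30, deadline=None)
    def test_strictly_order_preserving(self, c, seed):
        rng = np.random.default_rng(seed)
        vals = np.sort(rng.random(5))
        transformed = 1 / (1 + np.exp(c * vals + DEFAULT_OFFSET))
        assert np.all(np.diff(transformed) >= 0)
        distinct = np.diff(vals) > 0
        assert np.all(np.diff(transformed)[distinct] > 0)
        assert transformed.min() > 0 and transformed.max() < 1
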