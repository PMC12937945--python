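"""Shapley attribution: axioms, estimator agreement, and exports."""

import itertools
import math

import numpy as np
import pytest

from icipred.core_data import ValidationError
from icipred.interpret import (AttributionResult, fold_intersection,
                               global_importance, shapley_values,
                               top_variance_features, waterfall_export)


def brute_force_shapley(model_fn, x, background, m):
    """Direct Shapley formula over all coalitions (test-side oracle)."""
    phi = np.zeros(m)
    idx = np.arange(m)

    def v(S):
        X = np.repeat(x[None, :], background.shape[0], axis=0)
        off = [i for i in idx if i not in S]
        X[:, off] = background[:, off]
        return float(np.mean(model_fn(X)))

    for i in range(m):
        others = [j for j in range(m) if j != i]
        for r in range(m):
            for S in itertools.combinations(others, r):
                w = (math.factorial(len(S)) * math.factorial(m - len(S) - 1)
                     / math.factorial(m))
                phi[i] += w * (v(set(S) | {i}) - v(set(S)))
    return phi


def _nonlinear_model(X):
    return X[:, 0] * X[:, 1] + np.sin(X[:, 2]) + 0.5 * X[:, 0]


class TestExactMethod:
    def test_matches_brute_force_on_nonlinear_toy(self, rng):
        bg = rng.standard_normal((8, 3))
        x = rng.standard_normal(3)
        res = shapley_values(_nonlinear_model, bg, x[None, :], ["s"],
                             ["a", "b", "c"], method="exact")
        expected = brute_force_shapley(_nonlinear_model, x, bg, 3)
        np.testing.assert_allclose(res.values[0], expected, atol=1e-10)

    def test_dummy_axiom_ignored_feature_zero(self, rng):
        bg = rng.standard_normal((6, 4))
        x = rng.standard_normal(4)
        res = shapley_values(lambda X: X[:, 0] + X[:, 2] ** 2, bg,
                             x[None, :], ["s"], list("abcd"),
                             method="exact")
        assert res.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert res.values[0, 3] == pytest.approx(0.0, abs=1e-12)

    def test_linearity_for_additive_model(self, rng):
        w = np.array([1.5, -2.0, 0.3])
        bg = rng.standard_normal((50, 3))
        x = rng.standard_normal(3)
        res = shapley_values(lambda X: X @ w, bg, x[None, :], ["s"],
                             list("abc"), method="exact")
        np.testing.assert_allclose(res.values[0],
                                   w * (x - bg.mean(axis=0)), atol=1e-10)

    def test_symmetry_for_identical_features(self, rng):
        bg = rng.standard_normal((10, 2))
        bg[:, 1] = bg[:, 0]  # identically distributed backgrounds
        x = np.array([0.7, 0.7])
        res = shapley_values(lambda X: X[:, 0] + X[:, 1], bg, x[None, :],
                             ["s"], ["a", "b"], method="exact")
        assert res.values[0, 0] == pytest.approx(res.values[0, 1],
                                                 abs=1e-10)

    def test_feature_limit_enforced(self, rng):
        with pytest.raises(ValidationError, match="15"):
            shapley_values(lambda X: X.sum(1), rng.standard_normal((3, 16)),
                           rng.standard_normal((1, 16)), ["s"],
                           [f"f{i}" for i in range(16)], method="exact")


class TestSampledMethod:
    def test_local_accuracy_exact_by_construction(self, rng):
        bg = rng.standard_normal((10, 6))
        xs = rng.standard_normal((4, 6))
        res = shapley_values(_wide_model, bg, xs, list("wxyz"),
                             [f"f{i}" for i in range(6)], method="sampled",
                             budget=300, seed=0)
        np.testing.assert_allclose(res.base_values + res.values.sum(axis=1),
                                   res.model_outputs, atol=1e-8)

    def test_converges_to_exact_with_budget(self, rng):
        bg = rng.standard_normal((8, 6))
        x = rng.standard_normal((1, 6))
        exact = shapley_values(_wide_model, bg, x, ["s"],
                               [f"f{i}" for i in range(6)], method="exact")
        errs = []
        for budget in (2 ** 6, 4 * 2 ** 6):
            sampled = shapley_values(_wide_model, bg, x, ["s"],
                                     [f"f{i}" for i in range(6)],
                                     method="sampled", budget=budget,
                                     seed=1)
            errs.append(np.abs(sampled.values - exact.values).max())
        assert errs[1] <= errs[0]
        assert errs[1] < 0.05

    def test_budget_too_small_errors(self, rng):
        with pytest.raises(ValidationError, match="budget"):
            shapley_values(_wide_model, rng.standard_normal((3, 6)),
                           rng.standard_normal((1, 6)), ["s"],
                           [f"f{i}" for i in range(6)], method="sampled",
                           budget=5)

    def test_restricted_feature_subset(self, rng):
        bg = rng.standard_normal((6, 5))
        x = rng.standard_normal((1, 5))
        res = shapley_values(lambda X: X.sum(1), bg, x, ["s"], ["a", "c"],
                             method="exact", feature_idx=np.array([0, 2]))
        assert res.values.shape == (1, 2)
        np.testing.assert_allclose(
            res.base_values + res.values.sum(axis=1), res.model_outputs,
            atol=1e-10)


def _wide_model(X):
    return np.tanh(X[:, 0]) + 0.5 * X[:, 1] * X[:, 2] - X[:, 4]


class TestGlobalImportance:
    def _result(self, values, names):
        n, m = values.shape
        return AttributionResult([f"s{i}" for i in range(n)], names,
                                 values, np.zeros(n), values.sum(axis=1),
                                 "exact")

    def test_single_feature_rank_one(self):
        res = self._result(np.array([[0.5], [-0.2]]), ["only"])
        assert global_importance(res)["feature"].tolist() == ["only"]

    def test_zero_feature_ranked_last(self):
        res = self._result(np.array([[0.5, 0.0], [-0.3, 0.0]]), ["a", "b"])
        assert global_importance(res)["feature"].tolist() == ["a", "b"]

    def test_matches_independent_sort(self, rng):
        vals = rng.standard_normal((6, 5))
        names = list("abcde")
        df = global_importance(self._result(vals, names))
        manual = sorted(zip(np.abs(vals).mean(axis=0), names),
                        key=lambda t: (-t[0], t[1]))
        assert df["feature"].tolist() == [n for _, n in manual]


class TestFoldIntersection:
    def test_identical_rankings(self):
        r = [["a", "b", "c"]] * 3
        assert fold_intersection(r, 2) == {"a", "b"}

    def test_disjoint_rankings_empty(self):
        assert fold_intersection([["a", "b"], ["c", "d"]], 2) == set()

    def test_partial_overlap(self):
        r = [["a", "b", "c"], ["b", "a", "d"], ["b", "c", "a"]]
        assert fold_intersection(r, 2) == {"b"}

    def test_requires_two_folds(self):
        with pytest.raises(ValidationError):
            fold_intersection([["a"]], 1)


class TestWaterfall:
    def _result(self, rng, m=6):
        values = rng.standard_normal((1, m)) * 0.1
        base = np.array([0.4])
        return AttributionResult(["s0"], [f"f{i}" for i in range(m)],
                                 values, base,
                                 base + values.sum(axis=1), "exact")

    def test_rows_sum_to_model_output(self, rng):
        res = self._result(rng)
        df = waterfall_export(res, "s0", top_n=3)
        contrib = df.iloc[:-1]["value"].sum()
        assert contrib == pytest.approx(float(res.model_outputs[0]))

    def test_full_top_n_zero_remainder(self, rng):
        res = self._result(rng)
        df = waterfall_export(res, "s0", top_n=10)
        assert df[df["term"] == "remainder"]["value"].iloc[0] == 0.0

    def test_all_zero_attributions(self):
        res = AttributionResult(["s0"], ["a", "b"], np.zeros((1, 2)),
                                np.array([0.3]), np.array([0.3]), "exact")
        df = waterfall_export(res, "s0", top_n=1)
        assert df.iloc[:-1]["value"].sum() == pytest.approx(0.3)


def test_top_variance_features(rng):
    X = rng.standard_normal((50, 5))
    X[:, 2] *= 10
    X[:, 4] *= 5
    sel = top_variance_features(X, list("abcde"), 2)
    assert set(sel) == {2, 4}


def test_local_accuracy_violation_rejected(rng):
    with pytest.raises(ValidationError, match="local accuracy"):
        AttributionResult(["s"], ["a"], np.array([[0.5]]), np.array([0.0]),
                          np.array([0.9]), "exact")
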