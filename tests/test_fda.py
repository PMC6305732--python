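import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from focmts import fda
from focmts.preprocessing import NormalizationParams


def _identity_norm(names):
    return NormalizationParams(tuple(names), np.zeros(len(names)), np.ones(len(names)))


class TestScatterMatrices:
    def test_four_row_hand_computation(self):
        # two points per cohort in 2-D; matrices frozen from elementwise
        # outer-product arithmetic of the class-size-weighted definitions
        X_asd = np.array([[1.0, 2.0], [3.0, 4.0]])
        X_td = np.array([[0.0, 0.0], [2.0, 2.0]])
        s_b, s_w = fda.scatter_matrices(X_asd, X_td)
        np.testing.assert_allclose(s_b, [[1.0, 2.0], [2.0, 4.0]])
        np.testing.assert_allclose(s_w, [[8.0, 8.0], [8.0, 8.0]])

    def test_equal_means_zero_between_scatter(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        s_b, _ = fda.scatter_matrices(X, X)
        np.testing.assert_allclose(s_b, 0.0, atol=1e-12)

    def test_single_point_cohort_contributes_no_within_scatter(self):
        X_asd = np.array([[3.0, 1.0]])
        X_td = np.array([[0.0, 0.0], [1.0, 1.0]])
        _, s_w = fda.scatter_matrices(X_asd, X_td)
        # only the TD cohort contributes: 2 * [[0.5, 0.5], [0.5, 0.5]]
        np.testing.assert_allclose(s_w, [[1.0, 1.0], [1.0, 1.0]])

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_positive_semidefinite(self, seed):
        rng = np.random.default_rng(seed)
        X_asd = rng.standard_normal((7, 4))
        X_td = rng.standard_normal((9, 4))
        for mat in fda.scatter_matrices(X_asd, X_td):
            np.testing.assert_allclose(mat, mat.T)
            assert np.linalg.eigvalsh(mat).min() > -1e-9

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            fda.scatter_matrices(np.empty((0, 2)), np.ones((2, 2)))


class TestFitDirection:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_two_class_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        X_asd = rng.standard_normal((20, 5)) + rng.normal(0, 1, 5)
        X_td = rng.standard_normal((18, 5))
        w, _ = fda.fit_direction(X_asd, X_td)
        _, s_w = fda.scatter_matrices(X_asd, X_td)
        w_closed = np.linalg.solve(s_w, X_asd.mean(0) - X_td.mean(0))
        w_closed /= np.linalg.norm(w_closed)
        assert abs(w @ w_closed) > 1 - 1e-8
        assert np.linalg.norm(w) == pytest.approx(1.0)

    def test_orientation_asd_positive(self):
        rng = np.random.default_rng(3)
        X_td = rng.standard_normal((15, 3))
        X_asd = rng.standard_normal((15, 3)) + [2.0, 0.0, 0.0]
        w, _ = fda.fit_direction(X_asd, X_td)
        assert X_asd.mean(0) @ w > X_td.mean(0) @ w

    def test_one_dimensional_input(self):
        X_asd = np.array([[2.0], [3.0]])
        X_td = np.array([[0.0], [1.0]])
        w, _ = fda.fit_direction(X_asd, X_td)
        np.testing.assert_allclose(np.abs(w), [1.0])
        assert w[0] > 0  # ASD mean is larger

    def test_identical_class_means_degenerate(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        with pytest.raises(fda.DegenerateFitError):
            fda.fit_direction(X, X)

    def test_j_maximality_over_random_directions(self):
        rng = np.random.default_rng(7)
        X_asd = rng.standard_normal((30, 4)) + [1.0, 0.5, 0.0, 0.0]
        X_td = rng.standard_normal((28, 4))
        w, j = fda.fit_direction(X_asd, X_td)
        s_b, s_w = fda.scatter_matrices(X_asd, X_td)
        for _ in range(1000):
            v = rng.standard_normal(4)
            v /= np.linalg.norm(v)
            j_v = (v @ s_b @ v) / (v @ s_w @ v)
            assert j >= j_v - 1e-9

    def test_permuting_sample_order_changes_nothing(self):
        rng = np.random.default_rng(5)
        X_asd = rng.standard_normal((12, 3)) + 1.0
        X_td = rng.standard_normal((10, 3))
        w1, j1 = fda.fit_direction(X_asd, X_td)
        perm = rng.permutation(12)
        w2, j2 = fda.fit_direction(X_asd[perm], X_td[::-1])
        np.testing.assert_allclose(w1, w2, atol=1e-10)
        assert j1 == pytest.approx(j2)


class TestFitFdaTable:
    def test_fit_and_json_roundtrip(self):
        rng = np.random.default_rng(0)
        names = ["a", "b", "c"]
        tab = pd.DataFrame(rng.standard_normal((20, 3)), columns=names)
        tab.loc[:9, "a"] += 2.0
        tab["cohort"] = ["ASD"] * 10 + ["TD"] * 10
        model = fda.fit_fda(tab, names, _identity_norm(names))
        assert model.t_asd.mean() > model.t_td.mean()
        restored = fda.FdaModel.from_json(model.to_json())
        np.testing.assert_allclose(restored.w, model.w)
        np.testing.assert_allclose(restored.t_td, model.t_td)

    def test_unknown_subset_name_errors(self):
        tab = pd.DataFrame({"a": [1.0, 2.0], "cohort": ["ASD", "TD"]})
        with pytest.raises(Exception, match="nope"):
            fda.fit_fda(tab, ["nope"], _identity_norm(["a"]))


class TestScore:
    def test_axis_projection(self):
        model = _dummy_model(np.array([1.0, 0.0]))
        assert model.score(np.array([3.2, -7.0])) == pytest.approx(3.2)

    def test_linearity(self):
        model = _dummy_model(np.array([0.6, 0.8]))
        x = np.array([1.5, -2.0])
        assert model.score(3.0 * x) == pytest.approx(3.0 * model.score(x))

    def test_three_d_dot_product(self):
        w = np.array([0.5, -0.5, np.sqrt(0.5)])
        model = _dummy_model(w)
        x = np.array([2.0, 4.0, 6.0])
        expected = 2.0 * 0.5 + 4.0 * -0.5 + 6.0 * np.sqrt(0.5)
        assert model.score(x) == pytest.approx(expected)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            _dummy_model(np.array([1.0, 0.0])).score(np.array([1.0, 2.0, 3.0]))


def _dummy_model(w):
    names = tuple(f"m{i}" for i in range(len(w)))
    return fda.FdaModel(subset=names, w=w, norm=_identity_norm(names),
                        t_asd=np.array([1.0]), t_td=np.array([0.0]), j_value=1.0)


class TestCStatistic:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([2, 3], [0, 1], 1.0),
            ([0, 1], [2, 3], 0.0),
            ([1, 3], [2], 0.5),          # 1 win of 2 pairs, brute force
            ([1, 2, 3], [1, 2, 3], 0.5),  # identical sets by symmetry
            ([1], [1], 0.5),              # tie counts 1/2
        ],
    )
    def test_pair_counting(self, pos, neg, expected):
        assert fda.c_statistic(np.array(pos, float), np.array(neg, float)) == expected

    def test_against_sklearn_auc(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        pos = rng.standard_normal(40) + 0.8
        neg = rng.standard_normal(35)
        ours = fda.c_statistic(pos, neg)
        ref = sklearn_metrics.roc_auc_score(
            np.r_[np.ones(40), np.zeros(35)], np.r_[pos, neg])
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_brute_force_pair_fraction(self):
        rng = np.random.default_rng(2)
        pos = rng.integers(0, 5, 12).astype(float)  # heavy ties
        neg = rng.integers(0, 5, 9).astype(float)
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert fda.c_statistic(pos, neg) == pytest.approx(wins / (12 * 9))

    @given(shift=st.floats(0.1, 5.0), scale=st.floats(0.1, 5.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_invariant_under_increasing_transforms(self, shift, scale):
        rng = np.random.default_rng(0)
        pos = rng.standard_normal(15) + 0.5
        neg = rng.standard_normal(15)
        base = fda.c_statistic(pos, neg)
        assert fda.c_statistic(scale * pos + shift, scale * neg + shift) == base
        assert fda.c_statistic(np.exp(pos), np.exp(neg)) == base

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            fda.c_statistic(np.array([]), np.array([1.0]))


class TestConfusionMetrics:
    def test_all_correct(self):
        labels = np.array(["ASD", "TD", "ASD", "TD"])
        m = fda.confusion_metrics(labels, labels)
        assert (m["TPR"], m["TNR"], m["PPV"], m["NPV"]) == (1, 1, 1, 1)

    def test_all_predicted_positive(self):
        pred = np.array(["ASD", "ASD", "ASD"])
        truth = np.array(["ASD", "TD", "TD"])
        m = fda.confusion_metrics(pred, truth)
        assert m["TNR"] == 0
        assert m["NPV"] is None  # undefined, not zero

    def test_formula_arithmetic(self):
        truth = np.array(["ASD"] * 10 + ["TD"] * 10)
        pred = np.array(["ASD"] * 9 + ["TD"] + ["ASD"] * 2 + ["TD"] * 8)
        m = fda.confusion_metrics(pred, truth)
        assert (m["TP"], m["FN"], m["FP"], m["TN"]) == (9, 1, 2, 8)
        assert m["TPR"] == pytest.approx(0.9)
        assert m["TNR"] == pytest.approx(0.8)
        assert m["PPV"] == pytest.approx(9 / 11)
        assert m["NPV"] == pytest.approx(8 / 9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fda.confusion_metrics(np.array(["ASD"]), np.array(["ASD", "TD"]))
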