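"""Discriminants, networks, selection, and evaluation statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ifptml.models import (
    LinearModel,
    MetricsRecord,
    NetworkModel,
    auroc,
    confusion_metrics,
    fit_linear,
    fit_network,
    forward_stepwise,
    input_sensitivity,
    robustness,
)


class TestFitLinear:
    def test_symmetric_1d_boundary_at_zero(self, rng):
        n = 4000
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({"x": rng.normal(0, 1, n) + (2 * y - 1)})
        model = fit_linear(X, y)
        # score = a0 + a x; boundary at -a0/a ~ 0
        boundary = -model.intercept / model.coefficients["x"]
        assert abs(boundary) < 0.1

    def test_null_features_give_prior_accuracy(self, rng):
        n = 10_000
        X = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
        y = (rng.random(n) < 0.3).astype(int)
        model = fit_linear(X, y)
        ac = (model.predict(X) == y).mean()
        prior = max(y.mean(), 1 - y.mean())
        assert abs(ac - prior) < 0.02

    def test_matches_pooled_covariance_formula(self, rng):
        """Independent oracle: the closed-form Fisher direction."""
        n = 600
        X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
        y = (X["a"] - X["b"] + rng.normal(0, 1, n) > 0).astype(int)
        model = fit_linear(X, y)
        X0, X1 = X[y == 0].to_numpy(), X[y == 1].to_numpy()
        S = (((len(X0) - 1) * np.cov(X0, rowvar=False)
              + (len(X1) - 1) * np.cov(X1, rowvar=False))
             / (len(X0) + len(X1) - 2))
        w = np.linalg.solve(S, X1.mean(0) - X0.mean(0))
        np.testing.assert_allclose(list(model.coefficients.values()), w,
                                   rtol=1e-10)

    def test_close_to_sklearn_discriminant(self, rng):
        """Cross-check against the library discriminant (which pools the
        covariance with a slightly different normalization)."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        n = 2000
        X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
        y = (X["a"] + 0.5 * X["b"] + rng.normal(0, 1, n) > 0).astype(int)
        model = fit_linear(X, y)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        np.testing.assert_allclose(list(model.coefficients.values()),
                                   sk.coef_.ravel(), rtol=0.01)

    def test_score_is_affine_in_features(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (100, 2)), columns=["a", "b"])
        y = (X["a"] > 0).astype(int)
        model = fit_linear(X, y)
        X2 = X.copy()
        X2["b"] = X2["b"] + 1.0
        delta = model.score(X2) - model.score(X)
        np.testing.assert_allclose(delta, model.coefficients["b"], atol=1e-9)

    def test_single_class_training_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="both classes"):
            fit_linear(X, np.array([1, 1]))

    def test_json_round_trip(self, tmp_path):
        m = LinearModel(0.5, {"a": 1.0, "b": -2.0}, ("a", "b"))
        m.to_json(tmp_path / "m.json")
        back = LinearModel.from_json(tmp_path / "m.json")
        assert back == m


class TestForwardStepwise:
    def test_informative_feature_selected_first(self):
        successes = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            n = 400
            X = pd.DataFrame(r.normal(0, 1, (n, 10)),
                             columns=[f"f{i}" for i in range(10)])
            y = (X["f0"] + r.normal(0, 1, n) > 0).astype(int)
            sel = forward_stepwise(X, y)
            successes += bool(sel) and sel[0] == "f0"
        assert successes >= 18

    def test_type_one_error_control_on_noise(self):
        selected = 0
        for rep in range(40):
            r = np.random.default_rng(100 + rep)
            X = pd.DataFrame({"f0": r.normal(0, 1, 300)})
            y = r.integers(0, 2, 300)
            selected += len(forward_stepwise(X, y, alpha=0.05)) > 0
        # single candidate: entry rate ~ alpha; 3 SE binomial slack
        assert selected / 40 <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / 40)

    def test_max_features_cap(self, rng):
        n = 300
        X = pd.DataFrame(rng.normal(0, 1, (n, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = ((X["f0"] + X["f1"]) > 0).astype(int)
        sel = forward_stepwise(X, y, max_features=1)
        assert len(sel) == 1

    def test_forced_in_and_out(self, rng):
        n = 300
        X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
        y = (X["a"] > 0).astype(int)
        sel = forward_stepwise(X, y, forced_in=("c",), forced_out=("a",))
        assert sel[0] == "c" and "a" not in sel


class TestFitNetwork:
    def test_lnn_on_separable_blobs(self, rng):
        n = 2000
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({"a": rng.normal(0, 1, n) + 3 * y,
                          "b": rng.normal(0, 1, n) - 3 * y})
        lnn = fit_network(X, y, architecture=())
        assert (lnn.predict(X) == y).mean() > 0.95

    def test_mlp_beats_lnn_on_planted_interaction(self, rng):
        n = 8000
        x1, x2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        p = 1.0 / (1.0 + np.exp(-6 * x1 * x2))
        y = (rng.random(n) < p).astype(int)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        tmask = np.zeros(n, bool)
        tmask[: int(0.75 * n)] = True
        mlp = fit_network(X, y, tmask, architecture=(11,), seed=1)
        lnn = fit_network(X, y, tmask, architecture=(), seed=1)
        a_mlp = auroc(mlp.predict_proba(X[~tmask]), y[~tmask])
        a_lnn = auroc(lnn.predict_proba(X[~tmask]), y[~tmask])
        assert a_mlp >= a_lnn + 0.1

    def test_identical_seed_identical_weights(self, rng):
        n = 500
        X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
        y = (X["a"] > 0).astype(int)
        m1 = fit_network(X, y, architecture=(11,), seed=7)
        m2 = fit_network(X, y, architecture=(11,), seed=7)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_architecture_shapes(self, rng):
        n = 300
        X = pd.DataFrame(rng.normal(0, 1, (n, 7)),
                         columns=[f"f{i}" for i in range(7)])
        y = (X["f0"] > 0).astype(int)
        dln = fit_network(X, y, architecture=(10, 10), seed=0, epochs=5)
        assert [w.shape for w in dln.weights] == [(7, 10), (10, 10), (10, 1)]

    def test_json_round_trip_preserves_scores(self, rng, tmp_path):
        n = 200
        X = pd.DataFrame(rng.normal(0, 1, (n, 2)), columns=["a", "b"])
        y = (X["a"] > 0).astype(int)
        m = fit_network(X, y, architecture=(11,), seed=3, epochs=10)
        m.to_json(tmp_path / "net.json")
        back = NetworkModel.from_json(tmp_path / "net.json")
        np.testing.assert_allclose(back.score(X), m.score(X))


class TestConfusionMetrics:
    @pytest.mark.parametrize("pred0, pred1, stat, expected", [
        # observed-active row: Sn = pred1 / (pred0 + pred1)
        (7398, 18120, "sn", 71.0),
        (6517, 18907, "sn", 74.4),
    ])
    def test_sensitivity_from_counts(self, pred0, pred1, stat, expected):
        rec = MetricsRecord(subset="t", tp=pred1, fn=pred0, tn=0, fp=0)
        assert round(rec.sn, 1) == expected

    @pytest.mark.parametrize("pred0, pred1, expected", [
        (255190, 94292, 73.0),  # observed-inactive row: Sp = pred0/(p0+p1)
        (252534, 97042, 72.2),
    ])
    def test_specificity_from_counts(self, pred0, pred1, expected):
        rec = MetricsRecord(subset="t", tp=0, fn=0, tn=pred0, fp=pred1)
        assert round(rec.sp, 1) == expected

    def test_counting_from_vectors(self):
        pred = np.array([1, 1, 0, 0, 1, 0])
        obs = np.array([1, 0, 0, 1, 1, 0])
        rec = confusion_metrics(pred, obs)
        assert (rec.tp, rec.fp, rec.fn, rec.tn) == (2, 1, 1, 2)

    def test_perfect_predictions(self):
        obs = np.array([0, 0, 1, 1] * 10)
        rec = confusion_metrics(obs, obs)
        assert rec.sn == rec.sp == rec.ac == 100.0
        assert rec.chi2 == pytest.approx(rec.n)  # maximal for a 2x2 table

    def test_absent_class_gives_nan_sentinel_not_crash(self):
        rec = confusion_metrics(np.array([1, 1]), np.array([1, 1]))
        assert rec.sn == 100.0
        assert math.isnan(rec.sp) and math.isnan(rec.chi2)

    @pytest.mark.parametrize("table", [
        [[10, 5], [3, 12]], [[100, 1], [1, 100]], [[50, 50], [50, 50]],
        [[7, 13], [29, 1]], [[255190, 94292], [7398, 18120]]])
    def test_chi2_matches_hand_formula(self, table):
        (a, b), (c, d) = table
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        pred = np.concatenate([np.zeros(a), np.ones(b),
                               np.zeros(c), np.ones(d)]).astype(int)
        obs = np.concatenate([np.zeros(a + b), np.ones(c + d)]).astype(int)
        rec = confusion_metrics(pred, obs)
        assert rec.chi2 == pytest.approx(expected)
        assert rec.p_level == pytest.approx(stats.chi2.sf(expected, 1))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_random_scores_near_half(self, rng):
        n = 4000
        y = rng.integers(0, 2, n)
        scores = rng.normal(0, 1, n)
        n1, n0 = y.sum(), n - y.sum()
        se = math.sqrt((n + 1) / (12 * n1 * n0))
        assert abs(auroc(scores, y) - 0.5) < 3 * se

    def test_equals_all_pairs_oracle_with_ties(self, rng):
        scores = rng.integers(0, 5, 20).astype(float)  # forced ties
        y = rng.integers(0, 2, 20)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        pos = scores[y == 1]
        neg = scores[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auroc(scores, y) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(0, 1, 300)
        y = (scores + rng.normal(0, 1, 300) > 0).astype(int)
        assert auroc(scores, y) == pytest.approx(
            auroc(np.exp(scores), y))

    def test_single_class_sentinel(self):
        assert math.isnan(auroc([0.1, 0.9], [1, 1]))


class TestRobustness:
    def test_mean_of_reported_specificities(self):
        # three training-subset records with known Sp values
        recs = []
        for sp, tn_frac in [(73.0, None), (70.0, None), (70.6, None)]:
            tn = round(sp * 10)  # counts giving the desired Sp at 1 decimal
            recs.append(MetricsRecord("t", tp=1, fn=1, tn=tn, fp=1000 - tn))
        out = robustness(recs)
        assert out.mean["Sp"] == pytest.approx((73.0 + 70.0 + 70.6) / 3,
                                               abs=0.05)

    def test_mean_of_confusion_counts(self):
        counts = (255190, 244548, 246551)
        recs = [MetricsRecord("t", tp=5, fn=5, tn=c, fp=10) for c in counts]
        out = robustness(recs)
        assert out.mean["tn"] == pytest.approx(248763.0)

    def test_identical_inputs_zero_sdv(self):
        recs = [MetricsRecord("v", tp=10, fn=2, tn=20, fp=3)] * 3
        out = robustness(recs)
        assert out.sdv["Sn"] == 0.0 and out.sdv["tp"] == 0.0

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            robustness([MetricsRecord("t", 1, 1, 1, 1)])


class TestInputSensitivity:
    def test_zero_weight_feature_ratio_one(self, rng):
        n = 500
        X = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
        y = (X["a"] > 0).astype(int)
        model = LinearModel(0.0, {"a": 2.0, "b": 0.0}, ("a", "b"))
        sens = input_sensitivity(model, X, y)
        assert sens["b"] == pytest.approx(1.0, abs=1e-6)

    def test_constant_column_reports_zero(self, rng):
        n = 200
        X = pd.DataFrame({"a": rng.normal(0, 1, n), "z": np.zeros(n)})
        y = (X["a"] > 0).astype(int)
        model = fit_linear(X[["a"]], y, features=("a",))
        model = LinearModel(model.intercept,
                            {**model.coefficients, "z": 0.0}, ("a", "z"))
        sens = input_sensitivity(model, X, y)
        assert sens["z"] == 0.0

    def test_dominant_feature_has_largest_ratio(self, rng):
        n = 3000
        X = pd.DataFrame({"big": rng.normal(0, 1, n),
                          "small": rng.normal(0, 1, n),
                          "noise": rng.normal(0, 1, n)})
        y = (2.0 * X["big"] + 0.3 * X["small"]
             + rng.normal(0, 1, n) > 0).astype(int)
        model = fit_linear(X, y)
        sens = input_sensitivity(model, X, y)
        assert sens["big"] == max(sens.values())
        assert sens["big"] > sens["small"] > sens["noise"] - 0.01


@given(st.floats(-20, 20), st.floats(0.1, 5))
def test_linear_score_affine_property(a0, coef):
    model = LinearModel(a0, {"x": coef}, ("x",))
    X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
    s = model.score(X)
    assert s[1] - s[0] == pytest.approx(coef, rel=1e-9, abs=1e-9)
    assert s[0] == pytest.approx(a0, rel=1e-9, abs=1e-9)
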