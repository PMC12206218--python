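import numpy as np
import pytest
from sklearn.metrics import balanced_accuracy_score

from crosslight.estimators import (LinearModel, balanced_accuracy, fit_bw,
                                   fit_fa, fit_logistic, fit_naive, fit_pred,
                                   fit_rtlc, predict_labels)


class _DS:
    def __init__(self, X, y):
        self.X, self.y = np.asarray(X, float), np.asarray(y, int)


def _objective_logistic(X, y, w, b, lam):
    z = X @ w + b
    return np.mean(np.logaddexp(0, z) - y * z) + lam * np.sum(w ** 2)


def _grid_minimize(f, w_range=(-4, 4), b_range=(-4, 4), n=81, stages=3):
    """Progressively refined dense grid search over (w, b): the independent
    oracle for the convex fits (final resolution ~6e-5)."""
    ws = np.linspace(*w_range, n)
    bs = np.linspace(*b_range, n)
    for _ in range(stages):
        vals = np.array([[f(w, b) for b in bs] for w in ws])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        dw, db = ws[1] - ws[0], bs[1] - bs[0]
        w0, b0 = ws[i], bs[j]
        ws = np.linspace(w0 - dw, w0 + dw, n)
        bs = np.linspace(b0 - db, b0 + db, n)
    return w0, b0


@pytest.fixture()
def toy_1d():
    X = np.array([[-2.0], [-0.5], [0.8], [1.7]])
    y = np.array([0, 0, 1, 1])
    return X, y


class TestFitLogistic:
    def test_sign_and_optimality(self):
        m = fit_logistic(np.array([[-1.0], [1.0]]), np.array([0, 1]), 1.0)
        assert m.weights[0] > 0
        assert m.fit_report.gradient_norm <= 1e-8

    def test_symmetric_data_zero_intercept(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        m = fit_logistic(X, np.array([0, 0, 1, 1]), 0.5)
        assert abs(m.intercept) < 1e-6

    def test_matches_grid_search_oracle(self, toy_1d):
        X, y = toy_1d
        m = fit_logistic(X, y, 0.3)
        w_g, b_g = _grid_minimize(
            lambda w, b: _objective_logistic(X, y, np.array([w]), b, 0.3))
        assert abs(m.weights[0] - w_g) < 1e-3
        assert abs(m.intercept - b_g) < 1e-3

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(np.zeros((3, 1)), np.array([1, 1, 1]), 1.0)

    def test_deterministic(self, toy_1d):
        X, y = toy_1d
        m1, m2 = fit_logistic(X, y, 0.1), fit_logistic(X, y, 0.1)
        assert m1.weights[0] == m2.weights[0]
        assert m1.intercept == m2.intercept


class TestFitNaive:
    def test_empty_target_equals_baseline(self, toy_1d):
        X, y = toy_1d
        base = fit_logistic(X, y, 1.0)
        naive = fit_naive(_DS(X, y), _DS(np.empty((0, 1)), np.empty(0)), 1.0)
        np.testing.assert_array_equal(naive.weights, base.weights)
        assert naive.intercept == base.intercept

    def test_order_invariance(self, toy_1d, rng):
        X, y = toy_1d
        Xt = rng.normal(size=(4, 1))
        yt = np.array([0, 1, 0, 1])
        m1 = fit_naive(_DS(X, y), _DS(Xt, yt), 1.0)
        m2 = fit_naive(_DS(Xt, yt), _DS(X, y), 1.0)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-10)

    def test_equals_direct_pooled_fit(self, toy_1d, rng):
        X, y = toy_1d
        Xt = rng.normal(size=(4, 1))
        yt = np.array([0, 1, 0, 1])
        m = fit_naive(_DS(X, y), _DS(Xt, yt), 1.0)
        direct = fit_logistic(np.vstack([X, Xt]), np.concatenate([y, yt]), 1.0)
        np.testing.assert_allclose(m.weights, direct.weights, atol=1e-12)


class TestFitRtlc:
    def test_infinite_anchor_returns_source(self, toy_1d, rng):
        X, y = toy_1d
        src = fit_logistic(X, y, 1.0)
        Xt, yt = rng.normal(size=(6, 1)), np.array([0, 1, 0, 1, 0, 1])
        m = fit_rtlc(src, _DS(Xt, yt), 1e8)
        assert abs(m.weights[0] - src.weights[0]) < 1e-4
        assert abs(m.intercept - src.intercept) < 1e-4

    def test_vanishing_anchor_approaches_target_mle(self, rng):
        # non-separable target so the unregularized MLE exists
        Xt = np.array([[-1.5], [0.5], [-0.5], [1.5], [0.2], [-0.2]])
        yt = np.array([0, 0, 1, 1, 1, 0])
        src = fit_logistic(Xt, yt, 5.0)
        m = fit_rtlc(src, _DS(Xt, yt), 1e-8)
        mle = fit_logistic(Xt, yt, 0.0)
        assert abs(m.weights[0] - mle.weights[0]) < 1e-3
        assert abs(m.intercept - mle.intercept) < 1e-3

    def test_matches_grid_search_oracle(self, toy_1d):
        X, y = toy_1d
        src = fit_logistic(X, y, 1.0)
        Xt = np.array([[0.3], [-0.8], [1.1], [-0.1]])
        yt = np.array([1, 0, 1, 0])
        lam = 0.7
        m = fit_rtlc(src, _DS(Xt, yt), lam)

        def f(w, b):
            return (_objective_logistic(Xt, yt, np.array([w]), b, 0.0)
                    + lam * ((w - src.weights[0]) ** 2
                             + (b - src.intercept) ** 2))
        w_g, b_g = _grid_minimize(f)
        assert abs(m.weights[0] - w_g) < 1e-3
        assert abs(m.intercept - b_g) < 1e-3


class TestFitBw:
    @pytest.mark.parametrize("gamma,which", [(0.0, "source"), (1.0, "target")])
    def test_boundary_gammas(self, toy_1d, gamma, which, rng):
        X, y = toy_1d
        Xt = rng.normal(size=(4, 1))
        yt = np.array([0, 1, 1, 0])
        m = fit_bw(_DS(X, y), _DS(Xt, yt), gamma, 0.5)
        ref = fit_logistic(X if which == "source" else Xt,
                           y if which == "source" else yt, 0.5)
        np.testing.assert_allclose(m.weights, ref.weights, atol=1e-10)
        assert abs(m.intercept - ref.intercept) < 1e-10

    def test_gamma_half_matches_grid_oracle(self, toy_1d):
        X, y = toy_1d
        Xt = np.array([[0.4], [-1.2], [0.9], [-0.3]])
        yt = np.array([1, 0, 1, 0])
        lam = 0.2
        m = fit_bw(_DS(X, y), _DS(Xt, yt), 0.5, lam)

        def f(w, b):
            wv = np.array([w])
            return (0.5 * _objective_logistic(X, y, wv, b, 0.0)
                    + 0.5 * _objective_logistic(Xt, yt, wv, b, 0.0)
                    + lam * w ** 2)
        w_g, b_g = _grid_minimize(f)
        assert abs(m.weights[0] - w_g) < 1e-3
        # combined loss at solution beats both boundary fits
        for other in (fit_bw(_DS(X, y), _DS(Xt, yt), 0.0, lam),
                      fit_bw(_DS(X, y), _DS(Xt, yt), 1.0, lam)):
            assert f(m.weights[0], m.intercept) <= f(other.weights[0],
                                                     other.intercept) + 1e-12

    def test_gamma_out_of_range_rejected(self, toy_1d):
        X, y = toy_1d
        with pytest.raises(ValueError, match="gamma"):
            fit_bw(_DS(X, y), _DS(X, y), 1.5, 1.0)


class TestFitFa:
    def test_identical_domains_symmetric_blocks(self, toy_1d):
        X, y = toy_1d
        m = fit_fa(_DS(X, y), _DS(X, y), 1.0)
        _, w_src, w_tgt = np.split(m.weights, 3)
        np.testing.assert_allclose(w_src, w_tgt, atol=1e-6)

    def test_augmented_dimensions(self, toy_1d, rng):
        X, y = toy_1d
        Xt = rng.normal(size=(4, 1))
        m = fit_fa(_DS(X, y), _DS(Xt, np.array([0, 1, 0, 1])), 1.0)
        assert len(m.weights) == 3 * X.shape[1]
        assert m.feature_map == "fa_triple"

    def test_label_flip_opposes_target_block(self, toy_1d):
        X, y = toy_1d
        m = fit_fa(_DS(X, y), _DS(X, 1 - y), 0.1)
        _, w_src, w_tgt = np.split(m.weights, 3)
        assert w_src[0] > 0 > w_tgt[0]

    def test_matches_manual_augmentation(self, toy_1d, rng):
        X, y = toy_1d
        Xt = rng.normal(size=(4, 1))
        yt = np.array([1, 0, 0, 1])
        m = fit_fa(_DS(X, y), _DS(Xt, yt), 0.5)
        Z = np.vstack([np.hstack([X, X, 0 * X]),
                       np.hstack([Xt, 0 * Xt, Xt])])
        direct = fit_logistic(Z, np.concatenate([y, yt]), 0.5)
        np.testing.assert_allclose(m.weights, direct.weights, atol=1e-10)


class TestFitPred:
    def test_appended_column_is_source_score(self, toy_1d, rng):
        X, y = toy_1d
        src = fit_logistic(X, y, 1.0)
        Xt = rng.normal(size=(5, 1))
        yt = np.array([0, 1, 0, 1, 1])
        m = fit_pred(src, _DS(Xt, yt), 0.5)
        manual = np.hstack([Xt, (Xt @ src.weights + src.intercept)[:, None]])
        direct = fit_logistic(manual, yt, 0.5)
        np.testing.assert_allclose(m.weights, direct.weights, atol=1e-12)
        assert abs(m.intercept - direct.intercept) < 1e-12

    def test_zero_weight_source_equals_target_only(self, toy_1d):
        X, y = toy_1d
        src = LinearModel(weights=np.zeros(1), intercept=2.0,
                          method="baseline")
        m = fit_pred(src, _DS(X, y), 0.5)
        tgt_only = fit_logistic(X, y, 0.5)
        np.testing.assert_allclose(predict_labels(m, X),
                                   predict_labels(tgt_only, X))


class TestPredictAndScore:
    def test_tie_rule_and_constant_models(self):
        X = np.zeros((3, 2))
        m0 = LinearModel(weights=np.zeros(2), intercept=0.0, method="baseline")
        np.testing.assert_array_equal(predict_labels(m0, X), [1, 1, 1])
        m_neg = LinearModel(weights=np.zeros(2), intercept=-5.0,
                            method="baseline")
        np.testing.assert_array_equal(predict_labels(m_neg, X), [0, 0, 0])

    def test_matches_score_signs(self, rng):
        X = rng.normal(size=(20, 3))
        m = LinearModel(weights=rng.normal(size=3), intercept=0.3,
                        method="baseline")
        np.testing.assert_array_equal(
            predict_labels(m, X), (X @ m.weights + m.intercept >= 0))

    def test_balanced_accuracy_examples_and_sklearn_cross_check(self, rng):
        assert balanced_accuracy([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0
        assert balanced_accuracy([0, 0, 1], [1, 1, 1]) == 0.5
        # TP=3 FN=1 TN=2 FP=2
        y_true = [1, 1, 1, 1, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 0, 1, 1]
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.625)
        for _ in range(5):
            yt = rng.integers(0, 2, 30)
            yp = rng.integers(0, 2, 30)
            if len(np.unique(yt)) < 2:
                continue
            assert balanced_accuracy(yt, yp) == pytest.approx(
                balanced_accuracy_score(yt, yp))

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            balanced_accuracy([1, 1, 1], [0, 1, 0])


class TestModelSerialization:
    def test_json_round_trip_with_source_model(self, toy_1d):
        X, y = toy_1d
        src = fit_logistic(X, y, 1.0)
        m = fit_pred(src, _DS(X, y), 0.5)
        back = LinearModel.from_json(m.to_json())
        np.testing.assert_array_equal(back.weights, m.weights)
        np.testing.assert_array_equal(
            back.decision_function(X), m.decision_function(X))


class TestObjectiveInvariants:
    def test_da_objective_at_solution_beats_reference_points(self, toy_1d,
                                                             rng):
        X, y = toy_1d
        Xt = rng.normal(size=(4, 1))
        yt = np.array([0, 1, 1, 0])
        src = fit_logistic(X, y, 1.0)
        lam = 0.5
        m = fit_rtlc(src, _DS(Xt, yt), lam)

        def obj(w, b):
            return (_objective_logistic(Xt, yt, np.array([w]), b, 0.0)
                    + lam * ((w - src.weights[0]) ** 2
                             + (b - src.intercept) ** 2))
        assert obj(m.weights[0], m.intercept) <= obj(0.0, 0.0) + 1e-12
        assert obj(m.weights[0], m.intercept) <= obj(
            src.weights[0], src.intercept) + 1e-12
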