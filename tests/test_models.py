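"""PLS1 and BPNN calibration models plus the evaluation statistics."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from nirwood.metrics import Metrics, evaluate, rpd, secv_loo
from nirwood.models import BPNNRegressor, PLS1Regression, bpnn_train, pls_fit


class TestPLS1:
    def test_noiseless_full_rank_recovery(self, rng):
        X = rng.normal(size=(30, 4))
        beta = np.array([1.5, -2.0, 0.7, 3.0])
        y = X @ beta + 5.0
        m = pls_fit(X, y, n_components=4)
        assert np.abs(m.coef_ - beta).max() < 1e-8
        assert np.sqrt(np.mean((m.fitted_values_ - y) ** 2)) <= 1e-8

    def test_single_column_equals_simple_regression(self, rng):
        x = rng.normal(size=25)
        y = 2.0 * x + rng.normal(0, 0.2, 25)
        m = pls_fit(x[:, None], y, 1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert m.coef_[0] == pytest.approx(slope, rel=1e-10)
        assert m.intercept_ == pytest.approx(y.mean() - slope * x.mean(), rel=1e-10)

    def test_prediction_at_column_means_is_y_mean(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        m = pls_fit(X, y, 2)
        assert m.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(y.mean(), rel=1e-10)

    def test_agrees_with_sklearn_pls(self, rng):
        X = rng.normal(size=(25, 6))
        y = X[:, 0] - X[:, 4] + rng.normal(0, 0.3, 25)
        for ncomp in (1, 2, 3):
            ours = pls_fit(X, y, ncomp)
            ref = PLSRegression(n_components=ncomp, scale=False).fit(X, y)
            assert np.abs(ours.coef_ - ref.coef_.ravel()).max() < 1e-8

    def test_maximal_components_equal_ols(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        m = pls_fit(X, y, 5)
        A = np.column_stack([np.ones(30), X])
        ols = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.abs(m.coef_ - ols[1:]).max() < 1e-6
        assert m.intercept_ == pytest.approx(ols[0], abs=1e-6)

    def test_invalid_inputs_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            pls_fit(X, rng.normal(size=10), 10)
        with pytest.raises(ValueError):
            pls_fit(X, np.ones(10), 2)  # constant y


class TestBPNN:
    def test_same_seed_identical_weights(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, -1.0, 0.5, 0.2]) + rng.normal(0, 0.1, 30)
        a = BPNNRegressor(hidden_units=5, random_state=7).fit(X, y)
        b = BPNNRegressor(hidden_units=5, random_state=7).fit(X, y)
        assert np.array_equal(a.W1_, b.W1_)
        assert np.array_equal(a.w2_, b.w2_)
        c = BPNNRegressor(hidden_units=5, random_state=8).fit(X, y)
        assert not np.array_equal(a.W1_, c.W1_)

    def test_linear_target_converges(self, rng):
        X = rng.normal(size=(84, 5))
        y = X @ np.array([2.0, -1.0, 1.0, 0.5, -0.5]) + 10 + rng.normal(0, 0.05, 84)
        m = BPNNRegressor(hidden_units=3, random_state=1).fit(X, y)
        rmse = np.sqrt(np.mean((y - m.predict(X)) ** 2))
        assert rmse <= 0.05 * np.std(y, ddof=1)

    def test_beats_pls_on_quadratic_target(self):
        """Seeded simulation: on a quadratic response the nonlinear net should
        out-predict the linear model on held-out data in >= 90/100 runs."""
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(1000 + seed)
            Xc, Xp = r.normal(size=(84, 5)), r.normal(size=(41, 5))
            yc = (Xc @ np.array([1.0, 0, 0, 0, 0])) ** 2 + r.normal(0, 0.1, 84)
            yp = (Xp @ np.array([1.0, 0, 0, 0, 0])) ** 2 + r.normal(0, 0.1, 41)
            net = BPNNRegressor(random_state=seed).fit(Xc, yc)
            rmse_net = np.sqrt(np.mean((yp - net.predict(Xp)) ** 2))
            pls = PLS1Regression(n_components=5).fit(Xc, yc)
            rmse_pls = np.sqrt(np.mean((yp - pls.predict(Xp)) ** 2))
            wins += rmse_net < rmse_pls
        assert wins >= 90

    def test_default_architecture_from_inputs(self, rng):
        X = rng.normal(size=(20, 5))
        y = X.sum(axis=1) + rng.normal(0, 0.1, 20)
        m = bpnn_train(X, y, {"random_state": 0})
        assert m.W1_.shape == (5, 11)  # 2 * 5 + 1 hidden units

    def test_missing_seed_and_constant_target_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="random_state"):
            BPNNRegressor().fit(X, rng.normal(size=10))
        with pytest.raises(ValueError):
            BPNNRegressor(random_state=0).fit(X, np.ones(10))


class TestEvaluate:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=10)
        m = evaluate(y, y, "prediction")
        assert m.r_p == pytest.approx(1.0)
        assert m.rmsep == pytest.approx(0.0)

    def test_rpd_from_reported_statistics(self):
        # SD 2.23 GPa with RMSEP 0.76 -> RPD 2.93; with RMSEP 1.08 -> 2.06
        assert round(rpd(2.23, 0.76), 2) == 2.93
        assert round(rpd(2.23, 1.08), 2) == 2.06

    def test_rpd_identity_holds_on_records(self, rng):
        y = rng.normal(16, 2.5, 41)
        pred = y + rng.normal(0, 0.8, 41)
        m = evaluate(y, pred, "prediction")
        assert m.rpd == pytest.approx(m.sd / m.rmsep, abs=1e-9)
        assert m.sd == pytest.approx(np.std(y, ddof=1))
        assert abs(m.r_p) <= 1

    def test_calibration_record_has_no_rpd(self, rng):
        y = rng.normal(size=20)
        m = evaluate(y, y + 0.1, "calibration")
        assert m.rpd is None and m.sd is None
        assert m.r_c is not None

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.ones(5), np.arange(5.0), "prediction")


class TestSECV:
    def test_noiseless_linear_is_zero(self, rng):
        X = rng.normal(size=(12, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + 3.0
        assert secv_loo(PLS1Regression(3), X, y) <= 1e-8

    def test_matches_hand_rolled_holdout_loop(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        resid = []
        for i in range(5):
            tr = np.arange(5) != i
            m = PLSRegression(n_components=1, scale=False).fit(X[tr], y[tr])
            resid.append(y[i] - float(m.predict(X[i : i + 1]).ravel()[0]))
        resid = np.array(resid)
        expect = np.sqrt(np.sum((resid - resid.mean()) ** 2) / 4)
        assert secv_loo(PLS1Regression(1), X, y) == pytest.approx(expect, abs=1e-9)

    def test_invariant_to_sample_order(self, rng):
        X = rng.normal(size=(15, 4))
        y = X[:, 0] + rng.normal(0, 0.3, 15)
        a = secv_loo(PLS1Regression(2), X, y)
        perm = rng.permutation(15)
        b = secv_loo(PLS1Regression(2), X[perm], y[perm])
        assert a == pytest.approx(b, rel=1e-9)

    def test_bpnn_secv_reproducible(self, rng):
        X = rng.normal(size=(12, 2))
        y = X @ np.array([1.0, -0.5]) + rng.normal(0, 0.1, 12)
        spec = BPNNRegressor(hidden_units=3, max_epochs=200, n_restarts=1, random_state=5)
        assert secv_loo(spec, X, y) == pytest.approx(secv_loo(spec, X, y))
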