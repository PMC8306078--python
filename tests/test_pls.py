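"""PLS1 core: fit/predict exactness, LOO-CV oracle, LV rule, metrics."""
import numpy as np
import pytest

import fruitspec as fs
from fruitspec.pls import CVRecord, fit_pls, loo_cv, metrics, predict, select_lv


def brute_force_press(X, y, max_lv):
    """Literal refit-I-times oracle for leave-one-out PRESS."""
    n = len(y)
    press = np.zeros(max_lv)
    for k in range(1, max_lv + 1):
        for i in range(n):
            keep = np.arange(n) != i
            m = fit_pls(X[keep], y[keep], k)
            press[k - 1] += float((predict(m, X[i][None])[0] - y[i]) ** 2)
    return press


class TestFitPredict:
    def test_rank_one_problem_solved_by_one_component(self, rng):
        # centred orthogonal spectral columns, y a pure multiple of one
        Z = rng.normal(size=(10, 6))
        X, _ = np.linalg.qr(Z - Z.mean(axis=0))
        y = 3.0 * X[:, 2]
        m = fit_pls(X, y, 1)
        assert np.max(np.abs(predict(m, X) - y)) < 1e-10 * np.ptp(y)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_equals_ordinary_least_squares(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 14, 6
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        m = fit_pls(X, y, p)
        beta = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
        yh_ols = beta[0] + X @ beta[1:]
        assert np.max(np.abs(predict(m, X) - yh_ols)) < 1e-6 * np.ptp(y)

    def test_row_permutation_invariance(self, rng):
        X = rng.normal(size=(12, 8))
        y = rng.normal(size=12)
        perm = rng.permutation(12)
        m1 = fit_pls(X, y, 4)
        m2 = fit_pls(X[perm], y[perm], 4)
        assert np.allclose(m1.coef, m2.coef, atol=1e-12)
        assert abs(m1.intercept - m2.intercept) < 1e-12

    def test_centered_zero_row_predicts_mean(self, rng):
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        m = fit_pls(X, y, 2)
        # a new sample equal to the training column means is the centred origin
        assert abs(predict(m, m.x_mean[None])[0] - y.mean()) < 1e-12

    def test_sklearn_cross_check(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(20, 15))
        y = rng.normal(size=20)
        m = fit_pls(X, y, 5)
        sk = sklearn.PLSRegression(n_components=5, scale=False).fit(X, y[:, None])
        assert np.max(np.abs(predict(m, X) - sk.predict(X).ravel())) < 1e-8

    def test_rejects_degenerate_inputs(self, rng):
        X = rng.normal(size=(8, 4))
        with pytest.raises(ValueError, match="variance"):
            fit_pls(X, np.ones(8), 1)
        with pytest.raises(ValueError, match="infeasible"):
            fit_pls(X, rng.normal(size=8), 5)

    def test_training_rmse_non_increasing_in_components(self, rng):
        X = rng.normal(size=(16, 10))
        y = rng.normal(size=16)
        rmse = [
            metrics(y, predict(fit_pls(X, y, k), X), "cal").rmsec
            for k in range(1, 8)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(rmse, rmse[1:]))

    def test_noiseless_forward_model_recovered(self, noiseless_batch):
        b = noiseless_batch
        X = np.log10(b.spectra.values) * -1.0
        y = b.concentrations.values("ssc")
        # noiseless data rank equals the number of mixed constituents
        m = fit_pls(X, y, len(b.concentrations.constituents))
        r2 = metrics(y, predict(m, X), "cal").r2_cal
        assert r2 >= 0.99

    def test_column_mismatch_rejected(self, rng):
        m = fit_pls(rng.normal(size=(8, 5)), rng.normal(size=8), 2)
        with pytest.raises(ValueError, match="variables"):
            predict(m, rng.normal(size=(3, 4)))


class TestLooCV:
    def test_press_matches_brute_force_oracle_small(self, rng):
        X = rng.normal(size=(3, 4))
        y = rng.normal(size=3)
        cv = loo_cv(X, y, 1)
        oracle = brute_force_press(X, y, 1)
        assert np.allclose(cv.press, oracle, rtol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_press_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 15))
        p = int(rng.integers(5, 30))
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        max_lv = min(4, n - 2, p)
        cv = loo_cv(X, y, max_lv)
        oracle = brute_force_press(X, y, max_lv)
        assert np.max(np.abs(cv.press - oracle) / oracle) < 1e-8

    def test_duplicated_rows_drive_press_to_zero(self, rng):
        X = rng.normal(size=(6, 5))
        beta = rng.normal(size=5)
        y = X @ beta  # noiseless
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        cv = loo_cv(X2, y2, 5)
        # the left-out duplicate is still present, so prediction is exact
        assert cv.press[-1] < 1e-16 * float(y2 @ y2)

    def test_internal_consistency_of_stored_predictions(self, rng):
        X = rng.normal(size=(10, 7))
        y = rng.normal(size=10)
        cv = loo_cv(X, y, 3)
        recomputed = ((cv.predictions - cv.y_nom[:, None]) ** 2).sum(axis=0)
        assert np.array_equal(recomputed, cv.press) or np.allclose(
            recomputed, cv.press, rtol=1e-12
        )

    def test_infeasible_max_lv_clipped_with_warning(self, rng):
        X = rng.normal(size=(6, 10))
        y = rng.normal(size=6)
        with pytest.warns(UserWarning, match="clipped"):
            cv = loo_cv(X, y, 10)
        assert cv.press.size == 4  # I - 2

    def test_rmsecv_definition(self, rng):
        X = rng.normal(size=(9, 6))
        y = rng.normal(size=9)
        cv = loo_cv(X, y, 2)
        assert cv.rmsecv(2) == pytest.approx(np.sqrt(cv.press[1] / 9))


class TestSelectLV:
    @staticmethod
    def record(press):
        press = np.asarray(press, dtype=float)
        n = 100
        preds = np.zeros((n, press.size))
        y = np.zeros(n)
        preds[0] = np.sqrt(press)  # encode PRESS in a single residual
        return CVRecord(press=press, predictions=preds, y_nom=y, n_samples=n)

    def test_flat_tail_chosen_at_start_of_flat_region(self):
        # strictly decreasing then flat: the rule lands where PRESS stops
        # being significantly worse than the minimum
        press = [100.0, 40.0, 10.0, 1.02, 1.01, 1.0, 1.0]
        cv = self.record(press)
        assert select_lv(cv, prob_threshold=0.75) == 4

    def test_single_lv_record(self):
        assert select_lv(self.record([5.0])) == 1

    def test_identical_press_prefers_parsimony(self):
        assert select_lv(self.record([3.0, 3.0, 3.0])) == 1

    def test_never_exceeds_press_minimizer(self):
        press = [10.0, 5.0, 4.0, 8.0, 9.0]
        assert select_lv(self.record(press)) <= 3

    def test_raw_ratio_alternative(self):
        press = [2.0, 1.05, 1.0]
        assert select_lv(self.record(press), prob_threshold=1.1, method="ratio") == 2


class TestMetrics:
    def test_perfect_fit(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "cal")
        assert m.rmsec == 0 and m.r2_cal == 1

    def test_mean_predictor_scores_zero(self):
        y = np.array([0.0, 1.0, 2.0])
        m = metrics(y, np.full(3, y.mean()), "pred")
        assert m.r2_pred == pytest.approx(0.0)

    def test_hand_computed_example(self):
        m = metrics([0.0, 1.0, 2.0], [0.0, 1.0, 1.0], "cv")
        assert m.rmsecv == pytest.approx(np.sqrt(1.0 / 3.0))
        assert m.r2_cv == pytest.approx(0.5)

    def test_zero_variance_reference_reported_missing(self):
        m = metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0], "pred")
        assert m.r2_pred is None and m.rmsep is not None


class TestSerialization:
    def test_model_round_trip_with_chain(self, tmp_path, rng):
        from fruitspec.pretreatment import fit_apply, parse_chain

        grid = fs.make_wavelength_grid(900, 1145, 5)
        X = fs.SpectrumSet(0.1 + 0.8 * rng.random((12, grid.size)), grid, "NIR")
        chain = parse_chain("SM + MC")
        Xt = fit_apply(chain, X)
        y = rng.normal(size=12)
        m = fit_pls(Xt.values, y, 3)
        path = tmp_path / "model.npz"
        fs.save_model(m, path, chain=chain)
        m2, chain2 = fs.load_model(path)
        assert np.array_equal(m.coef, m2.coef)
        assert m.intercept == m2.intercept
        assert chain2.steps == chain.steps
        assert np.array_equal(chain2.column_means_, chain.column_means_)
        assert np.array_equal(predict(m, Xt.values), predict(m2, Xt.values))
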