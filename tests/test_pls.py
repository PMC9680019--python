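"""NIPALS PLS, its least-squares limit, random-subset CV and metrics."""

import numpy as np
import pytest

from thermocal.exceptions import DegenerateTargetError, DesignError, RankError
from thermocal.pls import (
    CVConfig,
    PredictionSummary,
    fit_pls,
    pls_predict,
    prediction_summary,
    random_subset_cv,
    regression_metrics,
    select_latent_variables,
)
from thermocal.spectra_core import SpectrumMeta


def _random_problem(seed, n=8, p=5, rank=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if rank is not None:
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        s[rank:] = 0
        X = U @ np.diag(s) @ Vt
    y = rng.normal(size=n)
    return X, y


def _meta_groups(labels):
    return [
        SpectrumMeta(str(lbl), 1.0, 25.0, float(i), 1, "calibration")
        for i, lbl in enumerate(labels)
    ]


class TestFitAndPredict:
    def test_rank_one_problem_fit_exactly_with_one_lv(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=6)
        t = rng.normal(size=12)
        X = np.outer(t, direction)
        y = 3.0 * t + 1.0
        model = fit_pls(X, y, n_lv=1)
        rmse, r2 = regression_metrics(y, pls_predict(model, X))
        assert rmse < 1e-10 and r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_full_rank_pls_equals_minimum_norm_least_squares(self, seed):
        """With as many components as the centred rank, PLS predictions
        match the pseudoinverse (minimum-norm least squares) oracle."""
        n, p = (6, 4) if seed % 2 else (8, 5)
        X, y = _random_problem(seed, n=n, p=p)
        Xc = X - X.mean(axis=0)
        rank = np.linalg.matrix_rank(Xc)
        b_oracle = np.linalg.pinv(Xc) @ (y - y.mean())
        model = fit_pls(X, y, n_lv=rank)
        np.testing.assert_allclose(
            pls_predict(model, X), Xc @ b_oracle + y.mean(), atol=1e-8
        )
        np.testing.assert_allclose(model.coef, b_oracle, atol=1e-8)

    def test_coef_equals_factor_recursion_and_scores_orthogonal(self):
        X, y = _random_problem(3, n=20, p=8)
        model = fit_pls(X, y, n_lv=5)
        Xc = X - model.x_mean
        # rebuild prediction from the W/P/q recursion factor by factor
        T = np.zeros((20, 5))
        Xd = Xc.copy()
        for k in range(5):
            T[:, k] = Xd @ model.weights[:, k]
            Xd -= np.outer(T[:, k], model.x_loadings[:, k])
        recursion = T @ model.y_loadings + model.y_mean
        np.testing.assert_allclose(recursion, Xc @ model.coef + model.y_mean, atol=1e-10)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        norms = np.linalg.norm(T, axis=0)
        assert np.max(np.abs(off) / np.outer(norms, norms)) < 1e-8

    def test_matches_sklearn_reference_implementation(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_problem(11, n=30, p=12)
        for n_lv in (1, 3, 6):
            ours = fit_pls(X, y, n_lv)
            ref = sklearn.PLSRegression(n_components=n_lv, scale=False).fit(X, y)
            np.testing.assert_allclose(
                pls_predict(ours, X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_constant_response_rejected(self):
        X, _ = _random_problem(0)
        with pytest.raises(DegenerateTargetError):
            fit_pls(X, np.full(8, 2.0), n_lv=1)

    def test_too_many_components_rejected(self):
        X, y = _random_problem(0, n=6, p=4)
        with pytest.raises(RankError):
            fit_pls(X, y, n_lv=6)

    def test_prediction_of_mean_spectrum_is_mean_response(self):
        X, y = _random_problem(5)
        model = fit_pls(X, y, n_lv=2)
        assert pls_predict(model, model.x_mean) == pytest.approx(model.y_mean)

    def test_prediction_is_affine(self):
        X, y = _random_problem(6)
        model = fit_pls(X, y, n_lv=2)
        x1, x2, alpha = X[0], X[1], 0.3
        blend = pls_predict(model, alpha * x1 + (1 - alpha) * x2)
        parts = alpha * pls_predict(model, x1) + (1 - alpha) * pls_predict(model, x2)
        assert blend == pytest.approx(parts, abs=1e-10)

    def test_model_round_trips_through_json(self, tmp_path):
        from thermocal.pls import PLSModel

        X, y = _random_problem(8)
        model = fit_pls(X, y, n_lv=2, preprocessing_tag="absorbance")
        path = tmp_path / "pls.json"
        model.to_json(path)
        back = PLSModel.from_json(path)
        np.testing.assert_array_equal(back.coef, model.coef)
        assert back.preprocessing_tag == "absorbance"


class TestRandomSubsetCV:
    def _linear_data(self, seed=0, n_groups=9, reps=3, p=6, noise=0.0):
        rng = np.random.default_rng(seed)
        direction = rng.normal(size=p)
        background = rng.normal(size=p)
        y_levels = np.linspace(2, 20, n_groups)
        X, y, labels = [], [], []
        for g, level in enumerate(y_levels):
            for _ in range(reps):
                X.append(level * direction + background + rng.normal(0, noise, p))
                y.append(level)
                labels.append(f"g{g}")
        return np.array(X), np.array(y), _meta_groups(labels)

    def test_each_unit_predicted_once_per_iteration(self):
        X, y, meta = self._linear_data(noise=0.05)
        cfg = CVConfig(n_splits=3, n_iterations=5, max_lv=3, seed=0)
        result = random_subset_cv(X, y, meta, cfg)
        counts = np.sum(~np.isnan(result.residuals), axis=(0, 2))
        assert np.all(counts == 5 * 3)  # n_iterations x max_lv per spectrum

    def test_noise_free_linear_data_has_vanishing_rmsecv_at_order_one(self):
        X, y, meta = self._linear_data(noise=0.0)
        result = random_subset_cv(X, y, meta, CVConfig(max_lv=3, seed=0))
        assert result.rmsecv[0] < 1e-8
        assert result.chosen_lv == 1

    def test_bit_reproducible_under_fixed_seed_and_seed_sensitive(self):
        X, y, meta = self._linear_data(noise=0.5)
        cfg = CVConfig(max_lv=4, seed=7)
        a = random_subset_cv(X, y, meta, cfg)
        b = random_subset_cv(X, y, meta, cfg)
        np.testing.assert_array_equal(a.residuals, b.residuals)
        c = random_subset_cv(X, y, meta, CVConfig(max_lv=4, seed=8))
        assert not np.array_equal(a.rmsecv, c.rmsecv)

    def test_grouping_by_sample_keeps_replicates_together(self):
        """Each group is held out exactly once per iteration, so no
        replicate of a held-out sample can sit in the training folds."""
        X, y, meta = self._linear_data(noise=0.1)
        result = random_subset_cv(X, y, meta, CVConfig(max_lv=2, seed=1, n_iterations=4))
        all_groups = {m.sample_id for m in meta}
        for iteration in result.held_out_groups:
            seen = [g for fold in iteration for g in fold]
            assert sorted(seen) == sorted(all_groups)  # partition: no overlap

    def test_too_few_groups_rejected(self):
        X, y, meta = self._linear_data(n_groups=2)
        with pytest.raises(DesignError):
            random_subset_cv(X, y, meta, CVConfig(n_splits=3))


class TestSelection:
    def test_parsimony_rule_on_flattening_curve(self):
        assert select_latent_variables(np.array([0.50, 0.20, 0.105, 0.10]), 0.10) == 3

    def test_increasing_curve_selects_one(self):
        assert select_latent_variables(np.array([0.1, 0.2, 0.3])) == 1

    def test_flat_curve_selects_one(self):
        assert select_latent_variables(np.array([0.2, 0.2, 0.2])) == 1


class TestMetrics:
    def test_perfect_prediction(self):
        rmse, r2 = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rmse == 0.0 and r2 == 1.0

    def test_mean_prediction_has_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0])
        _, r2 = regression_metrics(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_rmse_arithmetic(self):
        rmse, _ = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert rmse == pytest.approx(np.sqrt(1 / 3))

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(DegenerateTargetError):
            regression_metrics([2.0, 2.0], [1.0, 3.0])


class TestPredictionSummary:
    def test_exact_constant_predictions(self):
        s = prediction_summary([5.0, 5.0, 5.0], 5.0)
        assert s == PredictionSummary(rmse=0.0, mean=5.0, min=5.0, max=5.0, rsd=0.0)

    def test_spread_statistics(self):
        s = prediction_summary([4.9, 5.0, 5.1], 5.0)
        assert s.mean == pytest.approx(5.0)
        assert s.min == 4.9 and s.max == 5.1
        assert s.rsd == pytest.approx(2.0)

    def test_rmse_against_known_truth(self):
        s = prediction_summary([5.0, 5.0, 5.0, 7.0], 5.0)
        assert s.rmse == pytest.approx(1.0)

    def test_zero_mean_predictions_rejected(self):
        with pytest.raises(DegenerateTargetError):
            prediction_summary([-1.0, 1.0], 0.0)
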