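"""PLS engine: NIPALS fit, CV machinery, VIP, jackknife, DMOD, permutation."""

import numpy as np
import pytest
from scipy import stats

from alrpls import (
    assign_folds,
    choose_ncomp,
    dmod,
    fit_pls,
    jackknife_ci,
    misclassification,
    permutation_test,
    q_squared,
    vip,
)


@pytest.fixture()
def regression_data(rng):
    n, j = 60, 15
    x = rng.normal(size=(n, j))
    beta = np.zeros(j)
    beta[[1, 4, 9]] = [1.5, -1.0, 0.8]
    y = x @ beta + rng.normal(size=n) * 0.3
    return x, y


@pytest.fixture()
def separated_groups(rng):
    n = 40
    x = rng.normal(size=(n, 10))
    labels = np.array([1.0] * 20 + [-1.0] * 20)
    x[:20, :4] += 4.0  # widely separated groups
    return x, labels


class TestFit:
    def test_perfect_orthogonal_predictor(self, rng):
        """y equal to one column of an orthogonal design: one component fits exactly."""
        raw = rng.normal(size=(30, 6))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # orthogonal, mean-zero columns
        x = q * 3.0
        y = x[:, 2].copy()
        model = fit_pls(x, y, 1)
        assert model.r2(x, y) == pytest.approx(1.0, abs=1e-9)

    def test_first_weight_proportional_to_xty(self, regression_data):
        x, y = regression_data
        model = fit_pls(x, y, 3)
        xc = (x - x.mean(0)) / x.std(0, ddof=1)
        w = xc.T @ (y - y.mean())
        w /= np.linalg.norm(w)
        assert np.allclose(model.weights[:, 0], w, atol=1e-10)

    def test_full_rank_equals_ols(self, regression_data):
        x, y = regression_data
        model = fit_pls(x, y, x.shape[1])
        design = np.column_stack([np.ones(len(y)), x])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        assert np.allclose(model.predict(x), design @ beta, atol=1e-6)

    def test_scores_orthogonal(self, regression_data):
        x, y = regression_data
        model = fit_pls(x, y, 5)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_deflation_residual_orthogonal_to_scores(self, regression_data):
        x, y = regression_data
        model = fit_pls(x, y, 4)
        xs = model.transform_x(x)[:, model.kept]
        resid = xs - model.scores @ model.loadings.T
        assert np.abs(model.scores.T @ resid).max() < 1e-8

    def test_coef_and_scores_predict_identically(self, regression_data):
        x, y = regression_data
        model = fit_pls(x, y, 3)
        via_scores = model.y_mean + model.scores @ model.y_loadings
        assert np.allclose(via_scores, model.predict(x), atol=1e-8)

    def test_constant_column_dropped(self, regression_data):
        x, y = regression_data
        x = np.column_stack([x, np.full(len(y), 3.14)])
        model = fit_pls(x, y, 2)
        assert len(model.kept) == x.shape[1] - 1
        assert model.coef_full[-1] == 0.0

    def test_excess_components_truncated(self, rng):
        x = rng.normal(size=(10, 3))
        y = x @ np.array([1.0, 0.5, -0.2]) + rng.normal(size=10) * 0.1
        model = fit_pls(x, y, 50)
        assert model.n_components <= 3

    def test_discriminant_equals_regression_on_dummy(self, separated_groups):
        x, labels = separated_groups
        m_da = fit_pls(x, labels, 2, mode="discriminant")
        m_re = fit_pls(x, labels, 2, mode="regression")
        assert np.allclose(m_da.coef, m_re.coef, atol=1e-10)

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            fit_pls(rng.normal(size=(10, 4)), np.ones(10), 1)


class TestCrossValidation:
    def test_q2_matches_manual_cv_loop(self, regression_data):
        """Independent refit-per-fold PRESS pooling reproduces q_squared."""
        x, y = regression_data
        fold_assign = assign_folds(len(y), 7, seed=3)
        got = q_squared(x, y, 2, fold_assign=fold_assign)
        press = 0.0
        for g in range(7):
            tr = fold_assign != g
            model = fit_pls(x[tr], y[tr], 2)
            press += ((y[~tr] - model.predict(x[~tr])) ** 2).sum()
        expected = 1 - press / ((y - y.mean()) ** 2).sum()
        assert got == pytest.approx(expected, abs=1e-10)

    def test_choose_ncomp_deterministic(self, regression_data):
        x, y = regression_data
        a = choose_ncomp(x, y, seed=5)
        b = choose_ncomp(x, y, seed=5)
        assert a.chosen_components == b.chosen_components
        assert a.q2_per_component == b.q2_per_component
        assert np.array_equal(a.fold_assign, b.fold_assign)

    def test_two_latent_directions_recovered(self, rng):
        """y from 2 orthogonal X directions with small noise: A = 2 in >= 90%."""
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 80
            t1, t2 = r.normal(size=n), r.normal(size=n)
            p1, p2 = r.normal(size=20), r.normal(size=20)
            # dominant X direction is a weak y driver, so one component
            # cannot align with y and a second is genuinely needed
            x = 5 * np.outer(t1, p1) + np.outer(t2, p2) + r.normal(size=(n, 20)) * 0.1
            y = 0.3 * t1 + 1.5 * t2 + r.normal(size=n) * 0.1
            rep = choose_ncomp(x, y, seed=seed)
            hits += rep.chosen_components == 2
        assert hits >= 18

    def test_null_data_keeps_one_component(self, rng):
        """Pure-noise response: A = 1 and cumulative Q2 <= 0.05 in >= 90%."""
        good = 0
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            x = r.normal(size=(60, 30))
            y = r.normal(size=60)
            rep = choose_ncomp(x, y, seed=seed)
            q2 = rep.q2_per_component[rep.chosen_components - 1]
            good += (rep.chosen_components == 1) and (q2 <= 0.05)
        assert good >= 18

    def test_misclassification_zero_when_separable(self, separated_groups):
        x, labels = separated_groups
        fit_rate, cv_rate = misclassification(x, labels, 2, seed=4)
        assert fit_rate == 0.0
        assert cv_rate == 0.0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            misclassification(rng.normal(size=(10, 3)), np.ones(10), 1)

    def test_stratified_folds_balance_classes(self):
        labels = np.array([1.0] * 35 + [-1.0] * 35)
        fa = assign_folds(70, 7, seed=0, labels=labels)
        for g in range(7):
            grp = labels[fa == g]
            assert (grp == 1).sum() == 5
            assert (grp == -1).sum() == 5


class TestVip:
    def test_equal_weights_give_unit_vips(self, rng):
        raw = rng.normal(size=(40, 4))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        x = q.copy()
        y = x.sum(axis=1)  # equal loading on 4 orthogonal, equal-scale columns
        model = fit_pls(x, y, 1)
        v = vip(model)
        assert np.allclose(v.values, 1.0, atol=1e-8)

    def test_single_active_weight(self, rng):
        raw = rng.normal(size=(30, 5))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        x = q.copy()
        y = x[:, 0].copy()
        model = fit_pls(x, y, 1)
        v = vip(model)
        expected = np.zeros(5)
        expected[0] = np.sqrt(5)
        assert np.allclose(v.values, expected, atol=1e-8)

    def test_mean_squared_vip_is_one(self, regression_data):
        x, y = regression_data
        for a in (1, 2, 4):
            v = vip(fit_pls(x, y, a))
            assert (v.values**2).mean() == pytest.approx(1.0, abs=1e-10)


class TestJackknife:
    def test_identical_fold_coefficients_collapse_ci(self, rng):
        # exact linear relation at full rank: every leave-fold-out refit
        # recovers the same coefficient vector, so the CI collapses
        x = rng.normal(size=(35, 5))
        y = x @ np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        ci = jackknife_ci(x, y, 5, folds=7, seed=0)
        assert np.allclose(ci.se, 0.0, atol=1e-8)
        assert np.allclose(ci.lower, ci.estimate, atol=1e-6)

    def test_strong_driver_excludes_zero(self, regression_data):
        x, y = regression_data
        ci = jackknife_ci(x, y, 2, folds=7, seed=1)
        assert ci.excludes_zero[1]  # beta = 1.5 driver
        assert ci.excludes_zero[4]  # beta = -1.0 driver

    def test_null_feature_calibration(self):
        """A noise feature's CI excludes zero in about 5% of replicates."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            x = r.normal(size=(42, 6))
            y = x[:, 0] + r.normal(size=42) * 0.5
            ci = jackknife_ci(x, y, 1, folds=7, seed=seed)
            hits += bool(ci.excludes_zero[5])  # pure-noise column
        # binomial(200, 0.05) 99.5% band: [2, 20]
        assert 2 <= hits <= 20

    def test_too_few_folds_rejected(self, regression_data):
        x, y = regression_data
        with pytest.raises(ValueError, match="folds"):
            jackknife_ci(x, y, 1, folds=2)


class TestDmod:
    def test_sample_on_model_plane_has_zero_distance(self, rng):
        # rank-2 X: 2 components leave zero residual for every sample
        t = rng.normal(size=(25, 2))
        p = rng.normal(size=(2, 8))
        x = t @ p
        y = t[:, 0] + 0.5 * t[:, 1]
        model = fit_pls(x, y, 2)
        rep = dmod(model, x)
        assert np.allclose(rep.distances, 0.0, atol=1e-6)
        assert not rep.outliers.any()

    def test_corrupted_sample_flagged_as_maximum(self, rng):
        t = rng.normal(size=(40, 2))
        p = rng.normal(size=(2, 20))
        x = t @ p + rng.normal(size=(40, 20)) * 0.05
        y = t[:, 0] + rng.normal(size=40) * 0.1
        x[7, ::2] += rng.normal(size=10) * 5.0  # corrupt half the features
        model = fit_pls(x, y, 2)
        rep = dmod(model, x)
        assert rep.distances.argmax() == 7
        assert rep.outliers[7]

    def test_permutation_equivariance(self, regression_data, rng):
        x, y = regression_data
        model = fit_pls(x, y, 2)
        d = dmod(model, x).distances
        perm = rng.permutation(len(y))
        d_perm = dmod(model, x[perm]).distances
        assert np.allclose(d_perm, d[perm], atol=1e-12)


class TestPermutationTest:
    def test_strong_signal_gives_minimum_p(self, separated_groups):
        x, labels = separated_groups
        p, q2_obs, null = permutation_test(
            x, labels, 2, n_perm=99, seed=0, mode="discriminant"
        )
        assert p == pytest.approx(1 / 100)
        assert q2_obs > null.max()

    def test_p_bounded_below_by_plus_one_convention(self, rng):
        x = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        p, _, _ = permutation_test(x, y, 1, n_perm=19, seed=1)
        assert p >= 1 / 20

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(rng.normal(size=(30, 5)), rng.normal(size=30), 1, n_perm=10)
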