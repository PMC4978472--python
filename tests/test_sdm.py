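import numpy as np
import pandas as pd
import pytest
from scipy import stats

from antshift import climate, sdm


def brute_force_auc(y, scores):
    pos = [s for yy, s in zip(y, scores) if yy == 1]
    neg = [s for yy, s in zip(y, scores) if yy == 0]
    hits = 0.0
    for p in pos:
        for q in neg:
            hits += 1.0 if p > q else (0.5 if p == q else 0.0)
    return hits / (len(pos) * len(neg))


def toy_predictors(x):
    """Nine-variable predictor frame driven by one annual-mean vector."""
    x = np.asarray(x, dtype=float)
    return pd.DataFrame({
        "annual_max": x + 16, "annual_mean": x, "annual_min": x - 19,
        "jan_max": x - 11, "jan_mean": x - 15, "jan_min": x - 19,
        "jul_max": x + 16, "jul_mean": x + 12, "jul_min": x + 8,
    })


class TestMoransI:
    def test_smooth_gradient_detected(self, rng):
        coords = rng.uniform(0, 1000, (60, 2))
        values = coords[:, 0] / 100.0 + rng.normal(0, 0.1, 60)
        i_stat, p = sdm.morans_i(values, coords, neighbourhood_m=300.0)
        assert i_stat > 0
        assert p < 0.01

    def test_permutation_calibration(self, rng):
        """Analytical p-values should reject at close to the nominal rate
        on spatially shuffled data."""
        coords = rng.uniform(0, 1000, (50, 2))
        base = coords[:, 0] / 100.0 + rng.normal(0, 0.5, 50)
        rejections = 0
        for _ in range(200):
            _, p = sdm.morans_i(rng.permutation(base), coords, 300.0)
            rejections += p < 0.05
        assert 3 <= rejections <= 20  # ~5% of 200, with binomial slack

    def test_too_few_sites(self, rng):
        with pytest.raises(ValueError):
            sdm.morans_i([1, 2], rng.uniform(0, 10, (2, 2)), 5.0)

    def test_constant_field_undefined(self, rng):
        coords = rng.uniform(0, 100, (10, 2))
        i_stat, p = sdm.morans_i(np.ones(10), coords, 50.0)
        assert np.isnan(i_stat) and np.isnan(p)


class TestAutocovariate:
    def test_constant_response(self, rng):
        coords = rng.uniform(0, 300, (20, 2))
        np.testing.assert_allclose(sdm.build_autocovariate(np.ones(20), coords, 100.0), 1.0)

    def test_isolated_site_imputed_with_global_mean(self):
        coords = np.array([[0.0, 0.0], [10.0, 0.0], [5000.0, 5000.0]])
        response = np.array([1.0, 0.0, 1.0])
        auto = sdm.build_autocovariate(response, coords, 100.0)
        assert auto[2] == pytest.approx(response.mean())

    def test_matches_double_loop(self, rng):
        coords = rng.uniform(0, 500, (25, 2))
        response = rng.random(25)
        radius = 200.0
        auto = sdm.build_autocovariate(response, coords, radius)
        for i in range(25):
            num = den = 0.0
            for j in range(25):
                d = np.hypot(*(coords[i] - coords[j]))
                if 0 < d <= radius:
                    num += response[j] / d
                    den += 1.0 / d
            if den > 0:
                assert auto[i] == pytest.approx(num / den)

    def test_invalid_radius(self, rng):
        with pytest.raises(ValueError):
            sdm.build_autocovariate(np.ones(5), rng.uniform(0, 10, (5, 2)), 0.0)


class TestFitSDM:
    def test_monotone_truth_recovered(self, rng):
        x = rng.uniform(0, 15, 300)
        presence = rng.binomial(1, 1.0 / (1.0 + np.exp(-(x - 7.5))))
        preds = toy_predictors(x)
        auto = np.zeros(300)
        model = sdm.fit_sdm(presence, preds, auto)
        fitted = model.predict(preds, autocov=auto, clip=False)
        rho = stats.spearmanr(fitted, x).statistic
        assert rho > 0.95

    def test_hard_step_separates_classes(self, rng):
        """A noise-free step response is recovered as a clean split even
        though the likelihood is quasi-separable."""
        x = rng.uniform(0, 15, 200)
        presence = (x > 7.5).astype(int)
        model = sdm.fit_sdm(presence, toy_predictors(x), np.zeros(200))
        fitted = model.predict(toy_predictors(x), autocov=np.zeros(200), clip=False)
        assert fitted[x > 8.5].min() > fitted[x < 6.5].max()

    def test_refit_is_deterministic(self, rng):
        x = rng.uniform(0, 15, 100)
        presence = (x + rng.normal(0, 2, 100) > 7.5).astype(int)
        preds = toy_predictors(x)
        auto = rng.random(100)
        p1 = sdm.fit_sdm(presence, preds, auto).predict(preds, autocov=auto)
        p2 = sdm.fit_sdm(presence, preds, auto).predict(preds, autocov=auto)
        np.testing.assert_array_equal(p1, p2)

    def test_predictions_in_unit_interval(self, rng):
        x = rng.uniform(0, 15, 120)
        presence = rng.binomial(1, 1.0 / (1.0 + np.exp(-(x - 6.0))))
        model = sdm.fit_sdm(presence, toy_predictors(x), np.zeros(120))
        probs = model.predict(toy_predictors(rng.uniform(-5, 25, 80)))
        assert np.all((probs > 0) & (probs < 1))

    def test_single_class_rejected(self, rng):
        x = rng.uniform(0, 15, 50)
        with pytest.raises(ValueError):
            sdm.fit_sdm(np.ones(50), toy_predictors(x), np.zeros(50))

    def test_extrapolation_clipped_with_warning(self, rng, caplog):
        x = rng.uniform(5, 10, 100)
        presence = (x > 7.5).astype(int)
        model = sdm.fit_sdm(presence, toy_predictors(x), np.zeros(100))
        with caplog.at_level("WARNING", logger="antshift.sdm"):
            model.predict(toy_predictors(np.array([20.0, 7.0])))
        assert any("outside the training predictor range" in r.message
                   for r in caplog.records)


class TestAUC:
    def test_matches_concordant_pair_fraction_on_toys(self, rng):
        for _ in range(25):
            y = rng.integers(0, 2, 10)
            if y.min() == y.max():
                continue
            scores = np.round(rng.random(10), 1)  # coarse grid forces ties
            assert sdm.auc_score(y, scores) == pytest.approx(
                brute_force_auc(y, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        scores = rng.random(50)
        base = sdm.auc_score(y, scores)
        for transform in (np.exp, lambda s: s**3, lambda s: 10 * s - 4):
            assert sdm.auc_score(y, transform(scores)) == pytest.approx(base)


class TestCrossValidate:
    def test_perfectly_separable_toy(self, rng):
        x = np.r_[rng.uniform(0, 5, 60), rng.uniform(10, 15, 60)]
        presence = np.r_[np.zeros(60), np.ones(60)].astype(int)
        m = sdm.cross_validate(presence, toy_predictors(x), np.zeros(120), seed=3)
        assert m.auc == 1.0
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_acceptability_flag_threshold(self):
        ok = sdm.ValidationMetrics(auc=0.7, sensitivity=0.5, specificity=0.5,
                                   threshold_used=0.5, split_seed=0)
        bad = sdm.ValidationMetrics(auc=0.699, sensitivity=0.5, specificity=0.5,
                                    threshold_used=0.5, split_seed=0)
        assert ok.acceptable and not bad.acceptable

    def test_invalid_train_frac(self, rng):
        x = rng.uniform(0, 15, 40)
        with pytest.raises(ValueError):
            sdm.cross_validate((x > 7).astype(int), toy_predictors(x),
                               np.zeros(40), train_frac=1.5)


class TestAutocovariateInModel:
    def test_autocovariate_never_hurts_training_likelihood(self, rng):
        """The autocovariate adds a free linear term, so the fitted
        (penalised) model cannot lose training likelihood."""
        n = 150
        coords = rng.uniform(0, 1000, (n, 2))
        x = rng.uniform(0, 15, n)
        presence = ((x > 7) | (coords[:, 0] > 800)).astype(int)
        preds = toy_predictors(x)
        auto = sdm.build_autocovariate(presence, coords, 300.0)
        with_auto = sdm.fit_sdm(presence, preds, auto)
        without = sdm.fit_sdm(presence, preds, np.zeros(n))
        assert with_auto.result.llf >= without.result.llf - 1e-6


class TestMoranEigenvectors:
    def test_orthonormal_and_usable_in_model(self, rng):
        coords = rng.uniform(0, 1000, (80, 2))
        mem = sdm.moran_eigenvectors(coords, radius_m=400.0, k=4)
        assert mem.shape == (80, 4)
        np.testing.assert_allclose(mem.T @ mem, np.eye(4), atol=1e-8)
        x = rng.uniform(0, 15, 80)
        presence = rng.binomial(1, 1.0 / (1.0 + np.exp(-(x - 7.5))))
        model = sdm.fit_sdm(presence, toy_predictors(x), mem)
        probs = model.predict(toy_predictors(x))  # spatial terms at training mean
        assert np.all((probs >= 0) & (probs <= 1))


class TestUncertaintyBounds:
    def test_complement_of_mean_metrics(self):
        frame = pd.DataFrame({"auc": [0.8, 0.9], "sensitivity": [0.6, 0.64]})
        lo, hi = sdm.uncertainty_bounds(frame)
        assert lo == pytest.approx(1 - 0.85)
        assert hi == pytest.approx(1 - 0.62)
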