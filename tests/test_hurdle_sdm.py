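"""Hurdle BRT machinery: deviances, nt selection, thresholds, validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import orangsim as osm
from orangsim.hurdle_sdm import fit_component, split_hurdle_data
from orangsim.synthetic_landscape import PREDICTOR_NAMES


def brute_force_max_sss(p, y):
    best_t, best_s = None, -np.inf
    for t in sorted(set(p)):
        pred = p >= t
        s = pred[y == 1].mean() + (~pred[y == 0]).mean()
        if s > best_s + 1e-15:
            best_t, best_s = t, s
    return best_t


class TestDeviances:
    def test_poisson_examples(self):
        assert osm.poisson_deviance([2.0], [1.0]) == pytest.approx(
            2 * (2 * np.log(2) - 1), abs=1e-12)
        assert osm.poisson_deviance([0.0], [1.0]) == pytest.approx(2.0, abs=1e-12)

    def test_perfect_binomial_fit_approaches_zero(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        p = np.clip(y, 1e-9, 1 - 1e-9)
        assert osm.binomial_deviance(y, p) < 1e-7

    def test_binomial_clamps_degenerate_probabilities(self):
        # p exactly 0/1 contradicting y must stay finite
        assert np.isfinite(osm.binomial_deviance([1.0, 0.0], [0.0, 1.0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_agree_with_per_observation_formulas(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        y_bin = rng.integers(0, 2, n).astype(float)
        p = rng.uniform(0.01, 0.99, n)
        expect = np.mean([-2 * (yi * np.log(pi) + (1 - yi) * np.log(1 - pi))
                          for yi, pi in zip(y_bin, p)])
        assert osm.binomial_deviance(y_bin, p) == pytest.approx(expect, abs=1e-12)
        y_pois = rng.poisson(3.0, n).astype(float)
        mu = rng.uniform(0.5, 6.0, n)
        expect = np.mean([2 * ((yi * np.log(yi / mi) if yi > 0 else 0.0)
                               - (yi - mi)) for yi, mi in zip(y_pois, mu)])
        assert osm.poisson_deviance(y_pois, mu) == pytest.approx(expect, abs=1e-12)


class TestMaxSSS:
    def test_clean_separation_example(self):
        t = osm.max_sss_threshold(np.array([0.2, 0.3, 0.7, 0.9]),
                                  np.array([0, 0, 1, 1]))
        assert t == pytest.approx(0.7)

    def test_inverted_predictions_hit_boundary(self):
        p = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([0, 0, 1, 1])
        t = osm.max_sss_threshold(p, y)
        pred = p >= t
        sens = pred[y == 1].mean()
        spec = (~pred[y == 0]).mean()
        assert sens + spec == pytest.approx(1.0)

    def test_one_class_input_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            osm.max_sss_threshold(np.array([0.2, 0.6]), np.array([1, 1]))

    def test_equals_brute_force_scan(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            p = rng.random(50)
            y = (rng.random(50) < p).astype(int)
            if y.min() == y.max():
                continue
            assert osm.max_sss_threshold(p, y) == brute_force_max_sss(p, y)


@pytest.fixture(scope="module")
def signal_data():
    rng = np.random.default_rng(11)
    n = 400
    X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
    y = (rng.random(n) < expit(2.0 * X.a - 1.5 * X.b)).astype(float)
    return X, y


class TestFitComponent:
    def test_selected_nt_is_argmin_of_curve(self, signal_data):
        X, y = signal_data
        comp = fit_component(X, y, "binomial", 0.01, 2, 0.7,
                             tuple(range(10, 311, 25)), 5, seed=0)
        assert comp.nt == comp.nt_grid[int(np.argmin(comp.d_cv_curve))]
        assert comp.d_cv == comp.d_cv_curve.min()

    def test_same_seed_reproduces_selection(self, signal_data):
        X, y = signal_data
        a = fit_component(X, y, "binomial", 0.01, 2, 0.7,
                          tuple(range(10, 311, 25)), 5, seed=9)
        b = fit_component(X, y, "binomial", 0.01, 2, 0.7,
                          tuple(range(10, 311, 25)), 5, seed=9)
        assert a.nt == b.nt
        assert np.array_equal(a.d_cv_curve, b.d_cv_curve)

    def test_noise_response_selects_small_nt(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
        y = rng.integers(0, 2, 300).astype(float)
        grid = tuple(range(10, 1011, 25))
        comp = fit_component(X, y, "binomial", 0.01, 2, 0.7, grid, 5, seed=1)
        assert comp.nt <= grid[len(grid) // 10]

    def test_signal_model_beats_intercept_only(self, signal_data):
        X, y = signal_data
        comp = fit_component(X, y, "binomial", 0.01, 2, 0.7,
                             tuple(range(10, 511, 25)), 5, seed=2)
        null_dev = osm.binomial_deviance(y, np.full_like(y, y.mean()))
        assert comp.d_cv < null_dev

    def test_single_class_binomial_rejected(self):
        X = pd.DataFrame({"a": np.arange(20.0)})
        with pytest.raises(ValueError, match="both classes"):
            fit_component(X, np.ones(20), "binomial", 0.01, 1, 0.7, (10,), 5, 0)

    def test_fewer_rows_than_folds_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="folds"):
            fit_component(X, np.array([0.0, 1.0, 1.0]), "binomial",
                          0.01, 1, 0.7, (10,), 5, 0)


class TestOptimizeAndSimplify:
    def test_degenerate_grid_equals_fit_component(self, gridded, small_fit_config,
                                                  fitted_model):
        Xb, yb, _, _ = split_hurdle_data(gridded, list(PREDICTOR_NAMES))
        direct = fit_component(Xb, yb, "binomial", 0.01, 2, 0.7,
                               small_fit_config.nt_grid, 5,
                               small_fit_config.seed)
        assert fitted_model.binomial.nt == direct.nt
        assert fitted_model.binomial.d_cv == pytest.approx(direct.d_cv)

    def test_interaction_truth_prefers_deeper_trees(self):
        # response built on a pure pairwise product needs tc >= 2 to fit
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 300
            X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
            mu = np.exp(0.5 + 1.2 * X.a * X.b)
            ds = X.copy()
            ds["mean_count"] = rng.poisson(mu).astype(float)
            ds["presence"] = 1
            ds["source"] = "observed"
            cfg = osm.HurdleFitConfig(lr_grid=(0.01,), tc_grid=(1, 2, 3),
                                      nt_grid=tuple(range(10, 411, 25)),
                                      cv_folds=5, seed=seed)
            comps = [fit_component(X, ds["mean_count"].to_numpy(), "poisson",
                                   0.01, tc, 0.7, cfg.nt_grid, 5, seed)
                     for tc in cfg.tc_grid]
            best = min(comps, key=lambda c: c.d_cv)
            wins += best.tc >= 2
        assert wins >= 8

    def test_noise_predictor_dropped_first(self):
        rng = np.random.default_rng(13)
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["signal1", "signal2",
                                                           "noise"])
        p = expit(2.0 * X.signal1 - 1.5 * X.signal2)
        pres = (rng.random(n) < p).astype(int)
        cnt = rng.poisson(np.exp(1.0 + 0.8 * X.signal1))
        ds = X.copy()
        ds["presence"] = pres
        ds["mean_count"] = np.where(pres == 1, cnt, 0.0)
        ds["source"] = "observed"
        cfg = osm.HurdleFitConfig(lr_grid=(0.01,), tc_grid=(2,),
                                  nt_grid=tuple(range(10, 411, 25)),
                                  cv_folds=5, seed=5)
        model = osm.optimize_hurdle(ds, list(X.columns), cfg)
        _, report = osm.simplify_hurdle(model, ds, cfg)
        assert report.drop_order["binomial"][:1] == ["noise"]

    def test_infinite_se_simplifies_to_single_predictor(self, gridded,
                                                        small_fit_config,
                                                        fitted_model):
        _, report = osm.simplify_hurdle(fitted_model, gridded, small_fit_config,
                                        se_override=np.inf)
        assert len(report.simplified["binomial"].predictors) == 1
        assert len(report.simplified["poisson"].predictors) == 1

    def test_simplification_table_has_four_variants(self, gridded,
                                                    small_fit_config,
                                                    fitted_model):
        _, report = osm.simplify_hurdle(fitted_model, gridded, small_fit_config)
        assert list(report.table["variant"]) == [
            "saturated", "binomial", "poisson", "binomial and poisson"]


class TestEvaluate:
    def test_perfect_predictions_score_perfectly(self, gridded, fitted_model):
        # force components to reproduce observations via a mock-free path:
        # evaluate on a dataset where predictions equal observations is
        # approximated by the metric formulas directly
        y = np.array([0, 0, 1, 1, 1])
        p = np.array([0.01, 0.02, 0.98, 0.99, 0.97])
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(y, p) == 1.0
        assert osm.max_sss_threshold(p, y) == pytest.approx(0.97)

    def test_hand_computed_kappa(self):
        # confusion matrix TP=40 FN=10 FP=10 TN=40 -> kappa 0.6
        from sklearn.metrics import cohen_kappa_score
        y = np.concatenate([np.ones(50), np.zeros(50)]).astype(int)
        pred = np.concatenate([np.ones(40), np.zeros(10),
                               np.ones(10), np.zeros(40)]).astype(int)
        assert cohen_kappa_score(y, pred) == pytest.approx(0.6, abs=1e-12)

    def test_random_predictions_give_null_auc(self):
        rng = np.random.default_rng(14)
        y = np.repeat([0, 1], 500)
        p = rng.random(1000)
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(y, p) == pytest.approx(0.5, abs=0.05)

    def test_metrics_finite_and_ordered(self, gridded, fitted_model):
        met = osm.evaluate(fitted_model, gridded)
        assert 0 <= met.auc <= 1
        assert met.d_resid_binomial <= met.d_null_binomial
        assert met.d_resid_poisson <= met.d_null_poisson
        assert np.isfinite(met.mse) and np.isfinite(met.rmpe)
        assert len(met.thresholds) == 5


class TestPredictHurdle:
    def test_threshold_zero_equals_poisson_surface(self, landscape, fitted_model):
        import copy
        m = copy.copy(fitted_model)
        m.presence_threshold = 0.0
        out = osm.predict_hurdle(m, landscape.predictors)
        mu = m.poisson.predict(
            pd.DataFrame({k: v.ravel() for k, v in landscape.predictors.items()}))
        assert np.allclose(out.ravel(), mu)

    def test_threshold_above_one_zeroes_everything(self, landscape, fitted_model):
        import copy
        m = copy.copy(fitted_model)
        m.presence_threshold = 1.1
        assert (osm.predict_hurdle(m, landscape.predictors) == 0).all()

    def test_hurdle_composition_zero_below_positive_above(self, landscape,
                                                          fitted_model):
        out = osm.predict_hurdle(fitted_model, landscape.predictors)
        p = fitted_model.binomial.predict(
            pd.DataFrame({k: v.ravel() for k, v in landscape.predictors.items()}))
        below = (p < fitted_model.presence_threshold).reshape(landscape.shape)
        assert (out[below] == 0).all()
        assert (out[~below] > 0).all()

    def test_missing_layer_error_names_it(self, landscape, fitted_model):
        preds = dict(landscape.predictors)
        preds.pop("elevation")
        with pytest.raises(KeyError, match="elevation"):
            osm.predict_hurdle(fitted_model, preds)


class TestCrossDatasetValidation:
    def test_identity_relation_recovered(self):
        x = np.linspace(0, 10, 30)
        ols, rob = osm.cross_dataset_validation(x, x)
        assert ols.slope == pytest.approx(1.0, abs=1e-10)
        assert ols.intercept == pytest.approx(0.0, abs=1e-10)
        assert rob.slope == pytest.approx(1.0, abs=1e-6)

    def test_robust_fit_resists_gross_outlier(self):
        rng = np.random.default_rng(15)
        x = np.linspace(0, 10, 50)
        y = 2 * x + 1 + rng.normal(0, 0.1, 50)
        y[25] = 100.0
        ols, rob = osm.cross_dataset_validation(x, y)
        assert abs(rob.slope - 2) < abs(ols.slope - 2)

    def test_ols_matches_normal_equations(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=40)
        y = 1.5 + 0.7 * x + rng.normal(0, 0.3, 40)
        ols, _ = osm.cross_dataset_validation(x, y)
        A = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert ols.intercept == pytest.approx(beta[0], abs=1e-10)
        assert ols.slope == pytest.approx(beta[1], abs=1e-10)

    def test_zero_variance_predictions_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            osm.cross_dataset_validation(np.ones(10), np.arange(10.0))
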