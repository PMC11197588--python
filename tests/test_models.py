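"""Model contracts: LASSO/RF designs and fits, head routing, determinism."""

import numpy as np
import pytest

from maizeyield.models import (
    BaselineConfig,
    MODEL_KINDS,
    build_lasso_design,
    build_rf_design,
    fit_lasso,
    fit_rf,
    train_model,
)
from maizeyield.nn import TrainingConfig

TINY_NN = TrainingConfig(lstm_hidden=8, ann_width=4, max_epochs=3, batch_size=32, seed=0)


@pytest.fixture(scope="module")
def toy_panel():
    rng = np.random.default_rng(11)
    n = 80
    Xt = np.abs(rng.normal(2.0, 1.0, size=(n, 21, 5)))
    Xs = rng.normal(size=(n, 5))
    regions = rng.integers(1, 4, n)
    y = 5.0 + 0.3 * Xt[:, 10, 1] - 0.2 * Xt[:, 5, 2] + 0.5 * Xs[:, 0] + 0.1 * rng.normal(size=n)
    return Xt, Xs, regions, y


class TestLassoDesign:
    def test_column_count_and_layout(self, toy_panel):
        Xt = toy_panel[0]
        design = build_lasso_design(Xt)
        assert design.shape == (len(Xt), 147)  # 7 terms x 21 weeks
        # week-major layout: columns 0-6 belong to week 1
        np.testing.assert_allclose(design[:, 0], Xt[:, 0, 0])   # gdd
        np.testing.assert_allclose(design[:, 4], Xt[:, 0, 1] * Xt[:, 0, 2])  # kdd*prcp

    def test_zero_kdd_week_zeroes_its_interactions(self, toy_panel):
        Xt = toy_panel[0].copy()
        Xt[:, 3, 1] = 0.0
        design = build_lasso_design(Xt)
        week3 = design[:, 3 * 7: 4 * 7]
        np.testing.assert_allclose(week3[:, 4], 0.0)  # kdd*prcp
        np.testing.assert_allclose(week3[:, 5], 0.0)  # kdd*vpd
        assert not np.allclose(week3[:, 6], 0.0)      # prcp*vpd untouched

    def test_ndvi_and_soil_excluded(self, toy_panel):
        Xt = toy_panel[0].copy()
        design_before = build_lasso_design(Xt)
        Xt[:, :, 4] = 99.0  # NDVI column must not matter
        np.testing.assert_array_equal(design_before, build_lasso_design(Xt))


class TestLassoFit:
    def test_huge_penalty_gives_intercept_only(self, toy_panel):
        Xt, _, _, y = toy_panel
        model = fit_lasso(Xt, y, lasso_lambda=1e6)
        assert np.allclose(model.model.coef_, 0.0)
        np.testing.assert_allclose(model.predict(Xt, None, None), y.mean(), atol=1e-8)

    def test_zero_penalty_matches_normal_equations(self):
        """With lambda ~ 0 on a small full-rank problem, LASSO = OLS."""
        rng = np.random.default_rng(5)
        n = 10
        Xt = np.abs(rng.normal(1, 0.5, size=(n, 21, 5)))
        y = rng.normal(size=n)
        design = build_lasso_design(Xt)[:, :3]  # 10x3 full-rank subproblem
        mean, sd = design.mean(0), design.std(0)
        Z = (design - mean) / sd
        beta = np.linalg.solve(Z.T @ Z, Z.T @ (y - y.mean()))
        from sklearn.linear_model import Lasso
        lasso = Lasso(alpha=1e-9, max_iter=200000).fit(Z, y)
        np.testing.assert_allclose(lasso.coef_, beta, atol=1e-5)

    def test_default_lambda(self):
        assert BaselineConfig().lasso_lambda == 0.005


class TestRandomForest:
    def test_design_width(self, toy_panel):
        Xt, Xs, _, _ = toy_panel
        assert build_rf_design(Xt, Xs).shape[1] == 110

    def test_single_deep_tree_memorizes_training_point(self, toy_panel):
        Xt, Xs, _, y = toy_panel
        cfg = BaselineConfig(rf_trees=1, rf_mtry=110, rf_max_nodes=10000)
        model = fit_rf(Xt, Xs, y, cfg, seed=0)
        model.model.set_params(n_jobs=1)
        # bootstrap sampling: check points the tree saw verbatim predict well
        pred = model.predict(Xt, Xs, None)
        agree = np.isclose(pred, y, atol=1e-8).mean()
        assert agree > 0.5  # in-bag points reproduce their own labels

    def test_same_seed_same_predictions(self, toy_panel):
        Xt, Xs, _, y = toy_panel
        cfg = BaselineConfig(rf_trees=20, rf_mtry=37, rf_max_nodes=50)
        m1 = fit_rf(Xt, Xs, y, cfg, seed=4)
        m2 = fit_rf(Xt, Xs, y, cfg, seed=4)
        np.testing.assert_array_equal(m1.predict(Xt, Xs, None), m2.predict(Xt, Xs, None))

    def test_mtry_wider_than_design_rejected(self, toy_panel):
        Xt, Xs, _, y = toy_panel
        with pytest.raises(ValueError, match="mtry"):
            fit_rf(Xt, Xs, y, BaselineConfig(rf_mtry=111), seed=0)


class TestUniformContract:
    def test_unknown_kind_rejected(self, toy_panel):
        Xt, Xs, regions, y = toy_panel
        with pytest.raises(ValueError, match="unknown model kind"):
            train_model("svm", Xt, Xs, y, regions, 3)

    def test_mtl_heads_differ_across_regions(self, toy_panel):
        Xt, Xs, regions, y = toy_panel
        model = train_model("mtl", Xt, Xs, y, regions, 3, model_config=TINY_NN)
        same_input = Xt[:1], Xs[:1]
        preds = [model.predict(same_input[0], same_input[1], np.array([r]))[0]
                 for r in (1, 2, 3)]
        assert len({round(p, 10) for p in preds}) > 1  # heads are independent

    def test_alstm_ignores_region_labels(self, toy_panel):
        Xt, Xs, regions, y = toy_panel
        model = train_model("alstm", Xt, Xs, y, regions, 3, model_config=TINY_NN)
        p1 = model.predict(Xt[:5], Xs[:5], np.array([1, 2, 3, 1, 2]))
        p2 = model.predict(Xt[:5], Xs[:5], np.array([3, 3, 3, 3, 3]))
        np.testing.assert_array_equal(p1, p2)

    def test_out_of_range_region_rejected_at_predict(self, toy_panel):
        Xt, Xs, regions, y = toy_panel
        model = train_model("mtl", Xt, Xs, y, regions, 3, model_config=TINY_NN)
        with pytest.raises(ValueError, match="region"):
            model.predict(Xt[:2], Xs[:2], np.array([1, 7]))

    def test_prediction_invariant_to_batch_permutation(self, toy_panel):
        Xt, Xs, regions, y = toy_panel
        model = train_model("mtl", Xt, Xs, y, regions, 3, model_config=TINY_NN)
        perm = np.random.default_rng(0).permutation(len(Xt))
        direct = model.predict(Xt, Xs, regions)
        permuted = model.predict(Xt[perm], Xs[perm], regions[perm])
        np.testing.assert_allclose(direct[perm], permuted, atol=1e-6)

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_every_kind_fits_and_predicts(self, toy_panel, kind):
        Xt, Xs, regions, y = toy_panel
        model = train_model(
            kind, Xt, Xs, y, regions, 3, model_config=TINY_NN,
            baseline_config=BaselineConfig(rf_trees=10, rf_mtry=20, rf_max_nodes=30),
            seed=1,
        )
        pred = model.predict(Xt[:7], Xs[:7], regions[:7])
        assert pred.shape == (7,)
        assert np.isfinite(pred).all()


class TestCheckpoints:
    def test_neural_round_trip(self, toy_panel, tmp_path):
        from maizeyield.models import load_model, save_model
        Xt, Xs, regions, y = toy_panel
        model = train_model("mtl", Xt, Xs, y, regions, 3, model_config=TINY_NN)
        path = tmp_path / "mtl.ckpt.npz"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(back.predict(Xt[:9], Xs[:9], regions[:9]),
                                   model.predict(Xt[:9], Xs[:9], regions[:9]), atol=1e-6)
        assert back.kind == "mtl" and len(back.nets) == len(model.nets)

    def test_baseline_round_trip(self, toy_panel, tmp_path):
        from maizeyield.models import load_model, save_model
        Xt, Xs, _, y = toy_panel
        model = fit_lasso(Xt, y, 0.01)
        path = tmp_path / "lasso.joblib"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(back.predict(Xt, None, None),
                                   model.predict(Xt, None, None))


def test_lasso_recovers_active_week_signs():
    """On a linear zero-noise panel the selected coefficients carry the true
    signs: positive for GDD, negative for KDD, on the sensitivity-weighted
    weeks where the response is active."""
    from dataclasses import replace
    from maizeyield.panel import panel_to_arrays
    from maizeyield.synth import generate_panel
    from conftest import SMALL_CONFIG

    cfg = replace(SMALL_CONFIG, noise_sd=0.0, ndvi_noise_sd=0.0,
                  prcp_sat_week=1e9, vpd_threshold_week=0.0,
                  region_kdd_spread=0.0, gamma_awc=0.0,
                  intercept_spread=0.0, trend=0.0)
    bundle = generate_panel(cfg)
    arrays = panel_to_arrays(bundle)
    model = fit_lasso(arrays["Xt"], arrays["y"], lasso_lambda=0.005)
    coefs = model.model.coef_.reshape(21, 7)
    active = np.abs(coefs[:, :2]) > 1e-3  # gdd, kdd columns
    signs_ok = ((coefs[:, 0] > 0) | ~active[:, 0]) & ((coefs[:, 1] < 0) | ~active[:, 1])
    assert active.any()
    assert signs_ok.mean() >= 0.9
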