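import numpy as np
import pytest
from dataclasses import replace

from nichescreen import maxent
from nichescreen.maxent import (
    EngineConfig,
    cross_validate,
    expand_features,
    fit,
    permutation_importance,
    predict_logistic,
)

FAST = EngineConfig(n_replicates=3, n_background=2000)


class TestFeatureExpansion:
    @pytest.mark.parametrize("fcs,expected", [
        (("L",), 2),
        (("L", "Q", "P"), 5),          # 2 + 2 + 1
        (("L", "Q", "H", "P"), 5 + 2 * 2 * 16),
    ])
    def test_feature_counts_for_two_variables(self, fcs, expected):
        z = np.random.default_rng(0).uniform(size=(20, 2))
        x, fmap = expand_features(z, EngineConfig(feature_classes=fcs))
        assert x.shape == (20, expected)
        assert len(fmap) == expected

    def test_forward_hinge_formula(self):
        # x=0.5, knot 0.25 -> (0.5-0.25)/(1-0.25) = 1/3
        cfg = EngineConfig(feature_classes=("H",), n_hinge_knots=3)
        z = np.array([[0.5], [0.0]])
        x, fmap = expand_features(z, cfg)
        names = [f.name for f in fmap.features]
        j = next(i for i, f in enumerate(fmap.features)
                 if f.kind == "hinge_fwd" and abs(f.knot - 0.25) < 1e-9)
        assert x[0, j] == pytest.approx(1.0 / 3.0)
        # reverse hinge at knot 0.75 for x=0.5: (0.75-0.5)/0.75 = 1/3
        jr = next(i for i, f in enumerate(fmap.features)
                  if f.kind == "hinge_rev" and abs(f.knot - 0.75) < 1e-9)
        assert x[0, jr] == pytest.approx(1.0 / 3.0)

    def test_constant_variable_skipped_with_warning(self, caplog):
        z = np.column_stack([np.full(10, 0.3), np.linspace(0, 1, 10)])
        x, fmap = expand_features(z, EngineConfig(feature_classes=("L",)))
        assert x.shape[1] == 1
        assert fmap.features[0].variables == ("v2",)

    def test_hinges_come_in_forward_reverse_pairs(self):
        _, fmap = expand_features(
            np.random.default_rng(1).uniform(size=(10, 1)),
            EngineConfig(feature_classes=("H",), n_hinge_knots=4),
        )
        fwd = [f.knot for f in fmap.features if f.kind == "hinge_fwd"]
        rev = [f.knot for f in fmap.features if f.kind == "hinge_rev"]
        assert fwd == rev and len(fwd) == 4


class TestFit:
    def test_driver_dominates_noise(self, driver_sim):
        pres, bg = driver_sim
        model = fit(pres, bg, FAST, variables=["A", "B"])
        imp = permutation_importance(model, pres, bg, seed=0)
        assert imp["A"] > imp["B"]
        assert model.training_auc > 0.6
        # coefficient mass concentrated on A-derived features
        a_mass = sum(abs(c) for f, c in zip(model.feature_map.features, model.coefficients)
                     if "A" in f.variables)
        b_mass = sum(abs(c) for f, c in zip(model.feature_map.features, model.coefficients)
                     if f.variables == ("B",))
        assert a_mass > b_mass

    def test_huge_rm_shrinks_everything_to_uniform(self, driver_sim):
        pres, bg = driver_sim
        model = fit(pres, bg, replace(FAST, rm=1e4), variables=["A", "B"])
        assert model.k_params == 0
        assert np.allclose(predict_logistic(model, bg), 0.5)

    def test_duplicated_driver_keeps_auc(self, driver_sim):
        pres, bg = driver_sim
        base = fit(pres[:, :1], bg[:, :1], FAST, variables=["A"])
        dup = fit(
            np.column_stack([pres[:, 0], pres[:, 0]]),
            np.column_stack([bg[:, 0], bg[:, 0]]),
            FAST, variables=["A", "A2"],
        )
        assert abs(dup.training_auc - base.training_auc) < 0.02

    def test_bit_reproducible_under_fixed_config(self, driver_sim):
        pres, bg = driver_sim
        m1 = fit(pres, bg, FAST, variables=["A", "B"])
        m2 = fit(pres, bg, FAST, variables=["A", "B"])
        assert np.array_equal(m1.coefficients, m2.coefficients)
        assert m1.entropy_h == m2.entropy_h

    def test_increasing_rm_never_increases_k(self, driver_sim):
        pres, bg = driver_sim
        ks = [
            fit(pres, bg, replace(FAST, rm=rm), variables=["A", "B"]).k_params
            for rm in (0.5, 1.0, 2.0, 4.0, 8.0, 32.0, 128.0)
        ]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_too_few_presences_raises(self):
        with pytest.raises(maxent.DegenerateDataError):
            fit(np.array([[0.5]]), np.random.default_rng(0).uniform(size=(50, 1)))

    def test_all_constant_covariates_raise(self):
        with pytest.raises(maxent.DegenerateDataError):
            fit(np.full((5, 1), 0.5), np.full((50, 1), 0.5))

    def test_model_text_sidecar_roundtrip(self, driver_sim):
        pres, bg = driver_sim
        m = fit(pres, bg, FAST, variables=["A", "B"])
        back = maxent.NicheModel.from_text(m.to_text())
        assert np.array_equal(back.coefficients, m.coefficients)
        assert back.log_z == m.log_z
        x = bg[:100]
        assert np.allclose(predict_logistic(back, x), predict_logistic(m, x))


class TestPredictLogistic:
    def test_zero_coefficient_limit_is_half(self):
        rng = np.random.default_rng(2)
        pres = rng.uniform(size=(20, 1))
        bg = rng.uniform(size=(500, 1))
        model = fit(pres, bg, replace(FAST, rm=1e5), variables=["A"])
        n_bg = model.n_background
        # uniform raw = 1/n_bg, H = ln(n_bg), logistic = 0.5
        assert model.entropy_h == pytest.approx(np.log(n_bg))
        assert np.allclose(predict_logistic(model, bg), 0.5)

    def test_three_cell_toy_hand_arithmetic(self):
        # background eta = (0, ln2, ln4) -> raw = (1/7, 2/7, 4/7)
        cfg = EngineConfig(feature_classes=("L",))
        fmap = maxent.FeatureMap(
            variables=["x"], lo=np.array([0.0]), hi=np.array([1.0]),
            features=[maxent.Feature("L(x)", "linear", ("x",))],
        )
        bg = np.array([[0.0], [np.log(2) / np.log(4)], [1.0]])
        model = maxent.NicheModel(
            feature_map=fmap, coefficients=np.array([np.log(4)]),
            log_z=np.log(7.0), entropy_h=0.0, k_params=1, training_auc=1.0,
            config=cfg, n_presences=1, n_background=3,
        )
        raw = model.predict_raw(bg)
        assert np.allclose(raw, [1 / 7, 2 / 7, 4 / 7])
        h = -(raw * np.log(raw)).sum()
        model.entropy_h = h
        expected = np.exp(h) * raw / (1 + np.exp(h) * raw)
        assert np.allclose(predict_logistic(model, bg), expected)

    def test_monotone_in_single_positive_variable(self, driver_sim):
        pres, bg = driver_sim
        model = fit(pres[:, :1], bg[:, :1], FAST, variables=["A"])
        grid = np.linspace(0.05, 0.95, 30)[:, None]
        p = predict_logistic(model, grid)
        eta = model.eta(grid)
        # logistic is a monotone transform of eta
        assert np.all(np.diff(p)[np.diff(eta) > 0] >= -1e-12)

    def test_nan_rows_propagate(self, driver_sim):
        pres, bg = driver_sim
        model = fit(pres, bg, FAST, variables=["A", "B"])
        x = bg[:5].copy()
        x[2, 0] = np.nan
        out = predict_logistic(model, x)
        assert np.isnan(out[2]) and np.isfinite(out[[0, 1, 3, 4]]).all()


class TestPermutationImportance:
    def test_single_variable_gets_all(self, driver_sim):
        pres, bg = driver_sim
        model = fit(pres[:, :1], bg[:, :1], FAST, variables=["A"])
        imp = permutation_importance(model, pres[:, :1], bg[:, :1], seed=0)
        assert imp == {"A": 100.0}

    def test_symmetric_drivers_split_evenly(self):
        from scipy.special import expit
        rng = np.random.default_rng(21)
        n_pool = 40000
        a = rng.uniform(0, 1, n_pool)
        b = rng.uniform(0, 1, n_pool)
        keep = rng.random(n_pool) < expit(5 * (a - 0.5) + 5 * (b - 0.5))
        pres = np.column_stack([a[keep][:400], b[keep][:400]])
        bg = np.column_stack([rng.uniform(0, 1, 2000), rng.uniform(0, 1, 2000)])
        model = fit(pres, bg, FAST, variables=["A", "B"])
        imp = permutation_importance(model, pres, bg, seed=3)
        assert imp["A"] + imp["B"] == pytest.approx(100.0)
        assert 30 < imp["A"] < 70

    def test_sums_to_100_and_nonnegative(self, driver_sim):
        pres, bg = driver_sim
        model = fit(pres, bg, FAST, variables=["A", "B"])
        imp = permutation_importance(model, pres, bg, seed=5)
        assert min(imp.values()) >= 0
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-6)

    def test_zero_model_gives_all_zero_map(self, driver_sim, caplog):
        pres, bg = driver_sim
        model = fit(pres, bg, replace(FAST, rm=1e5), variables=["A", "B"])
        imp = permutation_importance(model, pres, bg, seed=0)
        assert set(imp.values()) == {0.0}


class TestCrossValidate:
    def test_single_replicate_equals_plain_fit(self, driver_sim):
        pres, bg = driver_sim
        cv = cross_validate(pres, bg, replace(FAST, n_replicates=1), variables=["A", "B"])
        direct = fit(pres, bg, replace(FAST, n_replicates=1), variables=["A", "B"])
        assert cv.mean_train_auc == pytest.approx(direct.training_auc)
        assert len(cv.replicates) == 1

    def test_fold_partition_deterministic(self, driver_sim):
        pres, bg = driver_sim
        a = cross_validate(pres, bg, FAST, variables=["A", "B"])
        b = cross_validate(pres, bg, FAST, variables=["A", "B"])
        assert [r.test_auc for r in a.replicates] == [r.test_auc for r in b.replicates]
        assert a.mean_importance == b.mean_importance

    def test_replicates_reduced_when_presences_scarce(self, driver_sim, caplog):
        pres, bg = driver_sim
        cv = cross_validate(pres[:4], bg, replace(FAST, n_replicates=10), variables=["A", "B"])
        assert len(cv.replicates) == 4

    def test_test_auc_not_above_train_auc_in_expectation(self, driver_sim):
        pres, bg = driver_sim
        gaps = []
        for seed in range(5):
            cv = cross_validate(
                pres[seed * 20 : seed * 20 + 60], bg,
                replace(FAST, n_replicates=3, seed=seed), variables=["A", "B"],
            )
            gaps.append(cv.mean_train_auc - cv.mean_test_auc)
        assert np.mean(gaps) > -0.02  # directional: training fits at least as well
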