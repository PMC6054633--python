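import numpy as np
import pytest

from fossilclim.calibration import (
    BRTRegressor,
    EnsembleReconstruction,
    MATRegressor,
    MLRCRegressor,
    RFRegressor,
    Reconstruction,
    WAPLSRegressor,
    WARegressor,
    cross_validate,
    make_model,
    reconstruct_ensemble,
    robust_loess,
)
from fossilclim.io import percentages
from oracles import mat_predict_bruteforce, wa_predict_bruteforce


def percent_matrix(scenario):
    pct = percentages(scenario.calibration)
    return pct.pollen_matrix().to_numpy(), scenario.climate.variable("t_jul")


class TestWA:
    def test_two_sample_toy(self, two_sample_calibration):
        X, y = two_sample_calibration
        wa = WARegressor().fit(X, y)
        np.testing.assert_allclose(
            wa.predict(np.array([[100.0, 0.0], [50.0, 50.0]])), [10.0, 15.0]
        )

    def test_constant_climate_predicts_constant(self):
        X = np.array([[60.0, 40.0], [30.0, 70.0], [50.0, 50.0]])
        y = np.array([12.0, 12.0, 12.0])
        wa = WARegressor().fit(X, y)
        np.testing.assert_allclose(wa.predict(X), 12.0)

    def test_sample_scale_invariance(self, small_scenario):
        X, y = percent_matrix(small_scenario)
        wa = WARegressor().fit(X, y)
        row = X[:3]
        np.testing.assert_allclose(wa.predict(row), wa.predict(row * 7.3), rtol=1e-10)

    def test_zero_abundance_taxon_dropped_with_warning(self):
        X = np.array([[50.0, 50.0, 0.0], [20.0, 80.0, 0.0], [70.0, 30.0, 0.0]])
        y = np.array([10.0, 14.0, 9.0])
        with pytest.warns(UserWarning, match="zero total abundance"):
            wa = WARegressor().fit(X, y)
        assert wa.optima_.shape == (2,)

    @pytest.mark.parametrize("deshrinking", ["inverse", "classical"])
    def test_matches_bruteforce(self, deshrinking, rng):
        X = rng.uniform(0, 50, size=(9, 5))
        y = rng.uniform(8, 18, size=9)
        Xn = rng.uniform(0, 50, size=(4, 5))
        model = WARegressor(deshrinking=deshrinking).fit(X, y)
        np.testing.assert_allclose(
            model.predict(Xn), wa_predict_bruteforce(X, y, Xn, deshrinking), rtol=1e-10
        )


class TestWAPLS:
    def test_one_component_equals_wa_inverse(self, small_scenario):
        X, y = percent_matrix(small_scenario)
        p_wapls = WAPLSRegressor(n_components=1).fit(X, y).predict(X)
        p_wa = WARegressor(deshrinking="inverse").fit(X, y).predict(X)
        assert np.abs(p_wapls - p_wa).max() < 1e-8

    def test_two_sample_toy_equals_wa(self, two_sample_calibration):
        X, y = two_sample_calibration
        model = WAPLSRegressor(n_components=1).fit(X, y)
        np.testing.assert_allclose(
            model.predict(np.array([[100.0, 0.0], [50.0, 50.0]])), [10.0, 15.0]
        )

    def test_training_rmse_non_increasing_in_components(self, small_scenario):
        X, y = percent_matrix(small_scenario)
        rmses = []
        for a in range(1, 5):
            pred = WAPLSRegressor(n_components=a).fit(X, y).predict(X)
            rmses.append(np.sqrt(((pred - y) ** 2).mean()))
        assert all(b <= a + 1e-9 for a, b in zip(rmses, rmses[1:]))

    def test_infeasible_rank_rejected(self, two_sample_calibration):
        X, y = two_sample_calibration
        with pytest.raises(ValueError, match="n_components"):
            WAPLSRegressor(n_components=2).fit(X, y)

    def test_component_selection_by_loo(self, small_scenario):
        X, y = percent_matrix(small_scenario)
        model = WAPLSRegressor(max_components=3).fit(X, y)
        assert 1 <= model.n_components_ <= 3


class TestMAT:
    def test_exact_match_k1(self, small_scenario):
        X, y = percent_matrix(small_scenario)
        model = MATRegressor(k=1).fit(X, y)
        np.testing.assert_allclose(model.predict(X[:5]), y[:5])

    def test_equidistant_pair_averaged(self):
        X = np.array([[80.0, 20.0], [20.0, 80.0]])
        y = np.array([10.0, 20.0])
        model = MATRegressor(k=2, weighting="none").fit(X, y)
        assert model.predict(np.array([[50.0, 50.0]]))[0] == pytest.approx(15.0)

    def test_matches_bruteforce_weighted(self, rng):
        X = rng.uniform(1, 50, size=(5, 4))
        y = rng.uniform(8, 18, size=5)
        Xn = rng.uniform(1, 50, size=(6, 4))
        model = MATRegressor(k=3).fit(X, y)
        np.testing.assert_allclose(
            model.predict(Xn), mat_predict_bruteforce(X, y, Xn, k=3), rtol=1e-10
        )

    def test_k_exceeding_n_rejected(self, two_sample_calibration):
        X, y = two_sample_calibration
        with pytest.raises(ValueError, match="k="):
            MATRegressor(k=3).fit(X, y)

    def test_predictions_within_calibration_range(self, small_scenario, rng):
        X, y = percent_matrix(small_scenario)
        model = MATRegressor().fit(X, y)
        novel = rng.uniform(0, 100, size=(20, X.shape[1]))
        pred = model.predict(novel)
        assert pred.min() >= y.min() and pred.max() <= y.max()


class TestMLRC:
    def test_pure_taxon_estimate_near_its_optimum(self):
        # two well-separated unimodal taxa plus a background taxon closing
        # the composition (closure would otherwise make proportions monotone)
        x = np.linspace(5, 20, 80)
        pa = 0.6 * np.exp(-((x - 9) ** 2) / 2)
        pb = 0.6 * np.exp(-((x - 16) ** 2) / 2)
        X = np.column_stack([pa, pb, 1 - pa - pb]) * 100
        model = MLRCRegressor(grid_points=301).fit(X, x)
        est = model.predict(np.array([[100.0, 0.0, 0.0]]))[0]
        # grid-search oracle over the fitted likelihood surface
        ll = model.log_likelihood(np.array([[100.0, 0.0, 0.0]]))[0]
        assert est == model.grid_[ll.argmax()]
        b0, b1, b2 = model.coefs_[0]
        fitted_optimum = -b1 / (2 * b2)
        assert b2 < 0 and not model.monotone_[0]
        assert abs(est - fitted_optimum) < 0.5

    def test_interior_optimum_beats_grid_edges(self, rng):
        x = np.linspace(5, 20, 60)
        pa = np.exp(-((x - 12) ** 2) / 6)
        pb = 1 - pa
        X = np.column_stack([pa, pb]) * 100
        model = MLRCRegressor(grid_points=301).fit(X, x)
        ll = model.log_likelihood(np.array([[90.0, 10.0]]))[0]
        assert ll.max() > ll[0] and ll.max() > ll[-1]

    def test_self_consistency_against_cv_error(self, small_scenario):
        X, y = percent_matrix(small_scenario)
        model = MLRCRegressor(grid_points=301).fit(X, y)
        cv = cross_validate(model, X, y, scheme="kfold", n_folds=5, seed=0)
        i = 7
        assert abs(model.predict(X[i : i + 1])[0] - y[i]) <= max(cv.rmsep, 1.0)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            MLRCRegressor().fit(np.zeros((5, 3)), np.arange(5.0))


class TestTreeEnsembles:
    def test_constant_target_constant_prediction(self, rng):
        X = rng.uniform(0, 100, size=(20, 4))
        y = np.full(20, 7.0)
        with pytest.warns(UserWarning, match="constant"):
            model = BRTRegressor(random_state=0).fit(X, y)
        np.testing.assert_allclose(model.predict(X[:5]), 7.0)

    @pytest.mark.parametrize("cls", [BRTRegressor, RFRegressor])
    def test_seed_reproducibility(self, cls, small_scenario):
        X, y = percent_matrix(small_scenario)
        p1 = cls(random_state=42).fit(X, y).predict(X[:10])
        p2 = cls(random_state=42).fit(X, y).predict(X[:10])
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("cls", [BRTRegressor, RFRegressor])
    def test_cv_skill_beats_climatology(self, cls, small_scenario):
        X, y = percent_matrix(small_scenario)
        cv = cross_validate(cls(random_state=1), X, y, scheme="kfold", n_folds=5, seed=1)
        assert cv.r2 > 0
        assert cv.rmsep < y.std()


class TestCrossValidate:
    def test_perfect_linear_system_has_near_zero_rmsep(self):
        x = np.linspace(10, 20, 12)
        X = np.column_stack([x, 100 - x])  # two taxa, proportions linear in x
        cv = cross_validate(WARegressor(), X, x, scheme="loo")
        assert cv.rmsep < 1e-8 and cv.r2 > 1 - 1e-10

    def test_loo_matches_hand_enumeration(self):
        X = np.array([[80.0, 20.0], [50.0, 50.0], [20.0, 80.0]])
        y = np.array([10.0, 12.0, 16.0])
        cv = cross_validate(WARegressor(), X, y, scheme="loo")
        expected = []
        for i in range(3):
            mask = np.ones(3, dtype=bool)
            mask[i] = False
            m = WARegressor().fit(X[mask], y[mask])
            expected.append(m.predict(X[i : i + 1])[0])
        np.testing.assert_allclose(cv.predictions, expected)

    def test_kfold_seed_reproducible(self, small_scenario):
        X, y = percent_matrix(small_scenario)
        cv1 = cross_validate(MATRegressor(), X, y, scheme="kfold", n_folds=5, seed=3)
        cv2 = cross_validate(MATRegressor(), X, y, scheme="kfold", n_folds=5, seed=3)
        assert cv1.rmsep == cv2.rmsep

    def test_unknown_scheme_rejected(self, two_sample_calibration):
        X, y = two_sample_calibration
        with pytest.raises(ValueError, match="scheme"):
            cross_validate(WARegressor(), X, y, scheme="bootstrap")


class TestLoess:
    def test_recovers_smooth_signal_from_noise(self, rng):
        x = np.linspace(0, 1, 200)
        truth = np.sin(2 * np.pi * x)
        y = truth + rng.normal(0, 0.3, 200)
        smoothed = robust_loess(x, y, span=0.3)
        assert ((smoothed - truth) ** 2).mean() < ((y - truth) ** 2).mean() / 3

    def test_outlier_downweighted_by_robustifying_iteration(self, rng):
        x = np.linspace(0, 1, 60)
        y = x.copy()
        y[30] += 10.0  # gross outlier
        robust = robust_loess(x, y, span=0.4, robustifying_iterations=1)
        plain = robust_loess(x, y, span=0.4, robustifying_iterations=0)
        i = 30
        assert abs(robust[i] - x[i]) < abs(plain[i] - x[i])


class TestEnsemble:
    def test_median_within_member_envelope_and_cv_present(self, small_scenario):
        s = small_scenario
        ens = reconstruct_ensemble(
            s.calibration, s.climate, s.fossil, climate_var="t_jul",
            methods=("WA", "WAPLS", "MAT"), seed=0, compute_cv=True,
        )
        stack = np.vstack([m.estimates for m in ens.members.values()])
        assert (ens.median >= stack.min(axis=0) - 1e-12).all()
        assert (ens.median <= stack.max(axis=0) + 1e-12).all()
        assert set(ens.cv_stats) == {"WA", "WAPLS", "MAT"}
        assert ens.members["MAT"].analogue_distances is not None

    def test_identical_members_give_identical_median(self):
        depths = np.linspace(1, 5, 10)
        est = np.sin(depths)
        members = {f"M{i}": Reconstruction(f"M{i}", depths, est.copy()) for i in range(6)}
        ens = EnsembleReconstruction(
            "t_jul", depths, members, np.median(
                np.vstack([m.estimates for m in members.values()]), axis=0
            ), est.copy(),
        )
        np.testing.assert_array_equal(ens.median, est)

    def test_failing_method_aborts_with_name(self, small_scenario):
        s = small_scenario
        with pytest.raises(ValueError, match="unknown calibration method"):
            reconstruct_ensemble(
                s.calibration, s.climate, s.fossil, methods=("WA", "NOPE"), seed=0,
            )

    def test_make_model_covers_all_methods(self):
        for name in ("WA", "WAPLS", "MAT", "MLRC", "BRT", "RF", "WA-PLS"):
            assert make_model(name, seed=1) is not None
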