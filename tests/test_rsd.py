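"""RSD-Hybrid-IMRTM: kinetic z-space, NLM weights, baseline prediction, GLM."""

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from rsdpet import (
    FrameSchedule,
    TAC,
    build_regressor_set,
    fit_beta,
    make_predictor,
    nlm_baseline,
    nlm_weights,
    percent_residuals,
    run_rsd_hybrid,
    scale_and_spill_fit,
    zscore_params,
)
from rsdpet.core_io import voxel_matrix
from rsdpet.rsd import (
    DegenerateMaskError,
    EmptyResidualError,
    KineticCoordinates,
    NLMWeights,
    PredictorSpec,
    RSDConfig,
    ResidualSeries,
    _nnls2,
)
from rsdpet.simulator import smooth_stand_in


class TestZScore:
    def test_two_voxel_sample_sd_convention(self):
        z = zscore_params(np.array([0.8, 1.2]), np.array([0.1, 0.3]), np.array([0.05, 0.06])).z
        assert np.allclose(z[:, 0], [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_constant_parameter_is_degenerate(self):
        with pytest.raises(DegenerateMaskError):
            zscore_params(np.array([1.0, 1.0, 1.0]), np.array([0.1, 0.2, 0.3]), np.array([0.1, 0.2, 0.3]))

    def test_standardization(self):
        rng = np.random.default_rng(0)
        z = zscore_params(rng.random(50), rng.random(50), rng.random(50)).z
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)


class TestNLMWeights:
    def test_identical_coordinates_full_weight(self):
        coords = KineticCoordinates(np.zeros((3, 3)))
        w = nlm_weights(coords, 0.5).w
        off = w[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_closed_form_value(self):
        z = np.zeros((2, 3))
        z[1, 0] = np.sqrt(0.5)  # squared distance 0.5
        w = nlm_weights(KineticCoordinates(z), 0.5).w
        assert w[0, 1] == pytest.approx(np.exp(-1.0))

    def test_zero_diagonal_and_symmetry(self):
        rng = np.random.default_rng(1)
        w = nlm_weights(KineticCoordinates(rng.random((10, 3))), 0.5).w
        assert np.all(np.diag(w) == 0)
        assert np.allclose(w, w.T)
        assert np.all((w >= 0) & (w <= 1))


class TestRegressorSet:
    def _data(self):
        tacs = np.arange(12, dtype=float).reshape(3, 4)
        imrtm = -np.ones((3, 4))
        return tacs, imrtm

    def test_all_measured_when_p_high(self):
        tacs, im = self._data()
        rs = build_regressor_set(tacs, np.ones(3), im)
        assert np.array_equal(rs.series, tacs)
        assert not rs.model_derived.any()

    def test_all_model_when_p_zero(self):
        tacs, im = self._data()
        rs = build_regressor_set(tacs, np.zeros(3), im)
        assert np.array_equal(rs.series, im)
        assert rs.model_derived.all()

    def test_threshold_application(self):
        tacs, im = self._data()
        rs = build_regressor_set(tacs[:2], np.array([0.04, 0.06]), im[:2])
        assert np.array_equal(rs.series[0], im[0])
        assert np.array_equal(rs.series[1], tacs[1])

    def test_missing_imrtm_for_flagged(self):
        tacs, _ = self._data()
        with pytest.raises(ValueError):
            build_regressor_set(tacs, np.zeros(3), None)


class TestNLMBaseline:
    def test_identical_regressors_convexity(self):
        series = np.tile(np.array([1.0, 2.0, 3.0]), (2, 1))
        rs = build_regressor_set(series, np.ones(2), None)
        w = NLMWeights(np.array([[0.0, 0.7], [0.7, 0.0]]), 0.5)
        out = nlm_baseline(w, rs)
        assert np.allclose(out, series)

    def test_weighted_mean_arithmetic(self):
        series = np.array([[4.0, 4.0], [8.0, 8.0], [0.0, 0.0]])
        rs = build_regressor_set(series, np.ones(3), None)
        w = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [1.0, 3.0, 0.0]])
        out = nlm_baseline(NLMWeights(w, 0.5), rs, fallback=series)
        assert np.allclose(out[2], 7.0)

    def test_bounded_by_contributors(self):
        rng = np.random.default_rng(2)
        series = rng.random((6, 5))
        rs = build_regressor_set(series, np.ones(6), None)
        w = nlm_weights(KineticCoordinates(rng.random((6, 3))), 0.5)
        out = nlm_baseline(w, rs)
        for j in range(6):
            others = np.delete(series, j, axis=0)
            assert np.all(out[j] <= others.max(axis=0) + 1e-12)
            assert np.all(out[j] >= others.min(axis=0) - 1e-12)

    def test_isolated_voxel_fallback(self):
        series = np.ones((2, 3))
        rs = build_regressor_set(series, np.ones(2), None)
        w = NLMWeights(np.zeros((2, 2)), 0.5)
        fb = 5.0 * np.ones((2, 3))
        with pytest.warns(UserWarning):
            out = nlm_baseline(w, rs, fallback=fb)
        assert np.allclose(out, 5.0)
        with pytest.raises(ValueError):
            nlm_baseline(w, rs)


class TestScaleAndSpill:
    def _setup(self):
        sched = FrameSchedule.uniform(75, 1.0)
        t = sched.mid_times
        c_nlm = 5.0 * np.exp(-0.02 * t) * (1 - np.exp(-0.5 * t))
        ref = 3.0 * np.exp(-0.08 * t) * (1 - np.exp(-0.7 * t))
        return sched, c_nlm, ref

    def test_pure_scale_recovery(self):
        sched, c_nlm, ref = self._setup()
        tac = TAC(1.5 * c_nlm, sched)
        bp = scale_and_spill_fit(tac, c_nlm, TAC(ref, sched), tD=36.0)
        assert bp.theta_nlm == pytest.approx(1.5, abs=1e-9)
        assert bp.theta_r == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(bp.values, 1.5 * c_nlm)

    def test_two_term_recovery(self):
        sched, c_nlm, ref = self._setup()
        tac = TAC(c_nlm + 0.2 * ref, sched)
        bp = scale_and_spill_fit(tac, c_nlm, TAC(ref, sched), tD=36.0)
        assert (bp.theta_nlm, bp.theta_r) == pytest.approx((1.0, 0.2), abs=1e-8)

    def test_nonnegativity_boundary(self):
        sched, c_nlm, ref = self._setup()
        tac = TAC(-c_nlm, sched)
        bp = scale_and_spill_fit(tac, c_nlm, TAC(ref, sched), tD=36.0)
        assert bp.theta_nlm == 0.0 and bp.theta_r == 0.0
        assert bp.degenerate

    def test_vectorized_nnls_matches_scipy(self):
        rng = np.random.default_rng(3)
        T, V = 20, 40
        A1, A2 = rng.random((V, T)), rng.random((V, T))
        Y = rng.standard_normal((V, T))
        w = rng.random(T) + 0.1
        theta = _nnls2(A1, A2, Y, w)
        sw = np.sqrt(w)
        for v in range(V):
            A = np.column_stack([A1[v] * sw, A2[v] * sw])
            expect, _ = scipy_nnls(A, Y[v] * sw)
            assert np.allclose(theta[v], expect, atol=1e-8)


class TestPercentResiduals:
    def _baseline(self, values):
        from rsdpet.rsd import BaselinePrediction

        return BaselinePrediction(np.asarray(values, float), 1.0, 0.0, np.asarray(values, float))

    def test_equal_curves_zero(self):
        sched = FrameSchedule.uniform(5)
        vals = np.array([1.0, 2.0, 3.0, 3.0, 2.0])
        r = percent_residuals(TAC(vals, sched), self._baseline(vals))
        assert np.allclose(r.values[r.valid], 0.0)

    def test_ten_percent_dip(self):
        sched = FrameSchedule.uniform(3)
        base = np.array([10.0, 10.0, 10.0])
        tac = np.array([10.0, 9.0, 10.0])
        r = percent_residuals(TAC(tac, sched), self._baseline(base))
        assert r.values[1] == pytest.approx(10.0)

    def test_scale_invariance(self):
        sched = FrameSchedule.uniform(6)
        rng = np.random.default_rng(4)
        base = rng.random(6) + 1.0
        tac = base * (1 + 0.05 * rng.standard_normal(6))
        r1 = percent_residuals(TAC(tac, sched), self._baseline(base))
        r2 = percent_residuals(TAC(7.3 * tac, sched), self._baseline(7.3 * base))
        assert np.allclose(r1.values, r2.values)

    def test_floor_excludes_low_baseline_frames(self):
        sched = FrameSchedule.uniform(4)
        base = np.array([0.01, 5.0, 10.0, 8.0])
        r = percent_residuals(TAC(np.ones(4), sched), self._baseline(base))
        assert not r.valid[0] and r.valid[1:].all()

    def test_all_below_floor(self):
        sched = FrameSchedule.uniform(3)
        with pytest.raises(EmptyResidualError):
            percent_residuals(TAC(np.ones(3), sched), self._baseline(np.zeros(3)))


class TestPredictor:
    def test_single_block_normalization_and_causality(self, schedule):
        p = make_predictor([(36.0, 46.0)], 10.0, schedule)
        assert p.fine_values.max() == pytest.approx(1.0)
        assert np.interp(36.0, p.fine_t, p.fine_values) == pytest.approx(0.0, abs=1e-9)
        assert np.all(p.values[schedule.mid_times <= 36.0] == 0.0)
        peak_i = np.argmax(p.fine_values)
        assert np.all(np.diff(p.fine_values[:peak_i + 1]) >= -1e-12)
        assert np.all(np.diff(p.fine_values[peak_i:]) <= 1e-12)

    def test_small_l_approaches_block_indicator(self, schedule):
        p = make_predictor([(36.0, 46.0)], 0.01, schedule)
        inside = (schedule.mid_times > 37.0) & (schedule.mid_times < 45.5)
        outside = schedule.mid_times < 35.5
        assert np.all(p.values[inside] > 0.95)
        assert np.all(p.values[outside] < 0.01)

    def test_two_blocks_superpose_before_normalization(self, schedule):
        pa = make_predictor([(36.0, 38.0)], 10.0, schedule)
        pb = make_predictor([(42.0, 44.0)], 10.0, schedule)
        pab = make_predictor([(36.0, 38.0), (42.0, 44.0)], 10.0, schedule)
        raw_ab = pab.fine_values / pab.lam
        assert np.all(raw_ab >= pa.fine_values / pa.lam - 1e-9)
        assert np.all(raw_ab >= pb.fine_values / pb.lam - 1e-9)

    def test_overlapping_blocks_rejected(self, schedule):
        with pytest.raises(ValueError):
            make_predictor([(36.0, 40.0), (38.0, 42.0)], 10.0, schedule)
        with pytest.raises(ValueError):
            make_predictor([], 10.0, schedule)


class TestFitBeta:
    def test_exact_multiple(self, schedule):
        p = make_predictor([(36.0, 46.0)], 10.0, schedule)
        assert fit_beta(4.0 * p.values, p) == pytest.approx(4.0)

    def test_zero_residuals(self, schedule):
        p = make_predictor([(36.0, 46.0)], 10.0, schedule)
        assert fit_beta(np.zeros(schedule.n_frames), p) == 0.0

    def test_monte_carlo_recovery(self, schedule):
        p = make_predictor([(36.0, 46.0)], 10.0, schedule)
        se = 1.0 / np.sqrt(np.sum(p.values**2))
        rng = np.random.default_rng(11)
        betas = [fit_beta(2.0 * p.values + rng.standard_normal(75), p) for _ in range(100)]
        assert abs(np.mean(betas) - 2.0) < 0.05 + 3 * se / 10
        assert np.all(np.abs(np.asarray(betas) - 2.0) < 4 * se)

    def test_no_predictor_support(self, schedule):
        p = PredictorSpec([(36.0, 46.0)], 10.0, 1.0, np.zeros(schedule.n_frames))
        with pytest.raises(ValueError):
            fit_beta(np.ones(schedule.n_frames), p)


class TestPipeline:
    def test_noise_free_null_recovers_baselines(self, null_study):
        st = null_study
        res = run_rsd_hybrid(st.baseline, st.phantom.striatum, st.phantom.cerebellum,
                             RSDConfig(coord_smooth_fwhm=0.0), ref=st.ref_tac)
        Y, _ = voxel_matrix(st.baseline, st.phantom.striatum)
        rel_rmse = np.sqrt(np.mean((res.baselines - Y) ** 2, axis=1)) / Y.mean(axis=1)
        assert np.mean(rel_rmse) < 0.01  # baseline recovery within 1% RMSE
        assert abs(np.nanmean(res.beta)) < 0.75  # beta centered near zero

    def test_noise_free_localized_contrast(self, localized_study_100):
        # coordinate regularization exists to suppress fit noise; on
        # noise-free data the exact per-voxel coordinates are better
        st = localized_study_100
        res = run_rsd_hybrid(smooth_stand_in(st.noise_free), st.phantom.striatum,
                             st.phantom.cerebellum, RSDConfig(coord_smooth_fwhm=0.0))
        rel = st.phantom.release_masks["localized"].labels
        idx = res.voxel_indices
        in_rel = rel[idx[:, 0], idx[:, 1], idx[:, 2]] > 0
        assert np.nanmean(res.beta[in_rel]) > 3 * abs(np.nanmean(res.beta[~in_rel]))
        assert np.nanmean(res.beta[in_rel]) > 0.5

    def test_global_release_triggers_more_replacement(self, localized_study_100):
        from rsdpet.simulator import PhantomSpec, simulate_study

        st_g = simulate_study(PhantomSpec(), "global", 100.0, 1, seed=902)[0]
        res_g = run_rsd_hybrid(st_g.noisy, st_g.phantom.striatum, st_g.phantom.cerebellum, RSDConfig())
        st_l = localized_study_100
        res_l = run_rsd_hybrid(st_l.noisy, st_l.phantom.striatum, st_l.phantom.cerebellum, RSDConfig())
        # smoothing spreads localized release beyond its clusters, so the
        # localized flag rate is itself well above the false-positive rate;
        # global release must still flag substantially more voxels
        assert res_g.diagnostics["replaced_fraction"] > res_l.diagnostics["replaced_fraction"] + 0.10

    def test_beta_map_geometry(self, localized_study_100):
        st = localized_study_100
        res = run_rsd_hybrid(st.noisy, st.phantom.striatum, st.phantom.cerebellum, RSDConfig())
        inside = st.phantom.striatum.labels > 0
        assert np.all(np.isfinite(res.beta_map.values[inside]) | np.isnan(res.beta_map.values[inside]))
        assert np.all(np.isnan(res.beta_map.values[~inside]))
        assert res.diagnostics["masked_out"] <= 0.01 * res.diagnostics["n_voxels"]
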