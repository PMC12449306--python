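"""Reference-tissue model fitting: MRTM, lp-ntPET, F-test, and IMRTM.

Forward-generation oracles build TACs directly from the model recursions
(explicit per-frame loops, independent of the package's vectorized
integration helpers) so that fitters can be checked for exact recovery.
"""

import numpy as np
import pytest

from rsdpet import (
    FrameSchedule,
    TAC,
    default_detection_basis,
    f_test,
    fit_lpntpet,
    fit_mrtm,
    imrtm,
    make_basis_set,
)
from rsdpet.kinetics import BasisFunction, DegenerateFitError, batch_lpntpet, batch_mrtm


def trapz_cumint(values, mids):
    """Oracle running integral: leading triangle + trapezoids (explicit loop)."""
    out = np.zeros(len(values))
    out[0] = 0.5 * values[0] * mids[0]
    for i in range(1, len(values)):
        out[i] = out[i - 1] + 0.5 * (values[i] + values[i - 1]) * (mids[i] - mids[i - 1])
    return out


def generate_model_tac(R1, k2, k2a, ref, mids, gamma=0.0, h=None):
    """Solve C(t) = R1 Cr + k2 I[Cr] - k2a I[C] - gamma I[C h] frame by frame.

    Each frame value appears linearly in its own integral increment, so the
    recursion is solved exactly per frame.
    """
    if h is None:
        h = np.zeros_like(ref)
    icr = trapz_cumint(ref, mids)
    C = np.zeros_like(ref)
    ict_prev = 0.0
    ich_prev = 0.0
    for i in range(len(ref)):
        a = 0.5 * mids[0] if i == 0 else 0.5 * (mids[i] - mids[i - 1])
        carry = 0.0 if i == 0 else C[i - 1]
        carry_h = 0.0 if i == 0 else C[i - 1] * h[i - 1]
        rhs = R1 * ref[i] + k2 * icr[i] - k2a * (ict_prev + a * carry) - gamma * (ich_prev + a * carry_h)
        C[i] = rhs / (1.0 + k2a * a + gamma * h[i] * a)
        ict_prev += a * (C[i] + carry)
        ich_prev += a * (C[i] * h[i] + carry_h)
    return C


@pytest.fixture(scope="module")
def ref_tac(schedule, analytic_ref):
    return TAC(analytic_ref, schedule)


class TestMRTM:
    def test_forward_generate_recovery(self, schedule, analytic_ref, ref_tac):
        truth = (0.9, 0.3, 0.12)
        C = generate_model_tac(*truth, analytic_ref, schedule.mid_times)
        fit = fit_mrtm(TAC(C, schedule), ref_tac)
        assert np.allclose((fit.R1, fit.k2, fit.k2a), truth, atol=1e-6)
        assert np.allclose(fit.fitted, C, atol=1e-8)

    def test_self_reference_symmetry(self, schedule, analytic_ref, ref_tac):
        fit = fit_mrtm(TAC(analytic_ref.copy(), schedule), ref_tac)
        assert fit.wrss == pytest.approx(0.0, abs=1e-14)
        assert fit.R1 == pytest.approx(1.0, abs=1e-6)
        assert fit.k2 == pytest.approx(fit.k2a, abs=1e-6)

    def test_normal_equations_oracle_10_frames(self):
        # explicit weighted normal-equations solution on a small fixture
        rng = np.random.default_rng(5)
        sched = FrameSchedule.uniform(10, 1.0)
        ref = np.abs(rng.random(10)) + 0.5
        y = np.abs(rng.random(10)) + 0.5
        w = rng.random(10) + 0.5
        tac = TAC(y, sched, weights=w)
        fit = fit_mrtm(tac, TAC(ref, sched))
        X = np.column_stack([
            ref,
            trapz_cumint(ref, sched.mid_times),
            -trapz_cumint(y, sched.mid_times),
        ])
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert np.allclose((fit.R1, fit.k2, fit.k2a), beta, atol=1e-10)

    def test_too_few_frames_in_window(self, schedule, analytic_ref, ref_tac):
        with pytest.raises(DegenerateFitError):
            fit_mrtm(TAC(analytic_ref.copy(), schedule), ref_tac, window=(0.0, 2.0))


class TestBasisSet:
    def test_unit_peak_and_zero_start(self):
        for b in default_detection_basis():
            assert b(b.tD) == pytest.approx(0.0)
            assert b(b.tP) == pytest.approx(1.0)
            assert np.all(b(np.linspace(0, 75, 500)) >= 0)

    def test_default_library_has_17_members(self):
        basis = default_detection_basis()
        assert len(basis) == 17
        assert basis[0].tP == 37.0 and basis[-1].tP == 51.0
        assert all(b.tD == 36.0 and b.alpha == 1.0 for b in basis)

    def test_unimodal_rise_and_decay(self):
        b = BasisFunction(tD=36.0, tP=42.0, alpha=1.0)
        t_rise = np.linspace(36.01, 42.0, 50)
        t_fall = np.linspace(42.0, 75.0, 50)
        assert np.all(np.diff(b(t_rise)) > 0)
        assert np.all(np.diff(b(t_fall)) < 0)

    def test_invalid_peak_time(self):
        with pytest.raises(ValueError):
            make_basis_set(36.0, [36.0])


class TestFTest:
    def test_equal_wrss(self):
        F, p = f_test(5.0, 5.0, 75, 3, 4)
        assert F == 0.0 and p == 1.0

    def test_worked_arithmetic(self):
        F, p = f_test(10.0, 8.0, 75, 3, 4)
        assert F == pytest.approx(2.0 / (8.0 / 71.0))
        assert 0 < p < 1

    def test_p_monotone_in_f(self):
        ps = [f_test(8.0 + d, 8.0, 75, 3, 4)[1] for d in (0.1, 0.5, 1.0, 5.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_perfect_rich_fit(self):
        F, p = f_test(1.0, 0.0, 75, 3, 4)
        assert np.isinf(F) and p == 0.0


class TestLpntpet:
    def test_forward_generate_recovery(self, schedule, analytic_ref, ref_tac):
        basis = default_detection_basis()
        true_b = basis[5]  # tP = 42
        h = true_b.at_frames(schedule)
        C = generate_model_tac(0.95, 0.25, 0.08, analytic_ref, schedule.mid_times, gamma=0.05, h=h)
        fit = fit_lpntpet(TAC(C, schedule), ref_tac, basis)
        assert fit.best_basis.tP == true_b.tP
        assert np.allclose((fit.R1, fit.k2, fit.k2a, fit.gamma), (0.95, 0.25, 0.08, 0.05), atol=1e-6)

    def test_null_data_gives_zero_gamma(self, schedule, analytic_ref, ref_tac):
        C = generate_model_tac(0.9, 0.3, 0.1, analytic_ref, schedule.mid_times)
        fit = fit_lpntpet(TAC(C, schedule), ref_tac, default_detection_basis())
        assert fit.gamma == pytest.approx(0.0, abs=1e-10)
        assert fit.F == pytest.approx(0.0, abs=1e-6) or fit.p > 0.99

    def test_best_wrss_beats_every_basis(self, schedule, sim_tacs):
        tac, ref = sim_tacs["rel400"], sim_tacs["ref"]
        basis = default_detection_basis()
        best = fit_lpntpet(tac, ref, basis)
        for b in basis:
            single = fit_lpntpet(tac, ref, [b])
            assert best.wrss <= single.wrss + 1e-12

    def test_wrss_never_exceeds_mrtm(self, schedule, sim_tacs):
        fit = fit_lpntpet(sim_tacs["rel400"], sim_tacs["ref"], default_detection_basis())
        assert fit.wrss <= fit.mrtm.wrss + 1e-12

    def test_empty_basis_degenerates_to_mrtm(self, schedule, sim_tacs):
        lp = fit_lpntpet(sim_tacs["rel400"], sim_tacs["ref"], [])
        m = fit_mrtm(sim_tacs["rel400"], sim_tacs["ref"])
        assert (lp.R1, lp.k2, lp.k2a) == pytest.approx((m.R1, m.k2, m.k2a))
        assert lp.gamma == 0.0 and lp.wrss == pytest.approx(m.wrss)

    def test_batch_matches_single_voxel(self, schedule, analytic_ref, ref_tac):
        rng = np.random.default_rng(7)
        basis = default_detection_basis()[:4]
        Y = np.stack([
            generate_model_tac(0.9 + 0.05 * i, 0.3, 0.1 + 0.01 * i, analytic_ref,
                               schedule.mid_times, gamma=0.02 * i, h=basis[i].at_frames(schedule))
            + 0.01 * rng.standard_normal(75)
            for i in range(4)
        ])
        out = batch_lpntpet(Y, analytic_ref, schedule, basis)
        for i in range(4):
            single = fit_lpntpet(TAC(Y[i], schedule), ref_tac, basis)
            assert out["gamma"][i] == pytest.approx(single.gamma, abs=1e-9)
            assert out["F"][i] == pytest.approx(single.F, rel=1e-6)
            assert out["R1"][i] == pytest.approx(single.R1, abs=1e-9)


class TestIMRTM:
    def test_mrtm_consistent_tac_is_fixed_point(self, schedule, analytic_ref, ref_tac):
        C = generate_model_tac(0.9, 0.3, 0.1, analytic_ref, schedule.mid_times)
        res = imrtm(TAC(C, schedule), ref_tac, tD=36.0, n_iter=5)
        for it in res.iterates[1:]:
            assert np.allclose(it, C, atol=1e-8)

    def test_k2a_zero_converges_in_one_iteration(self, schedule, analytic_ref, ref_tac):
        # without the self-integral term the update does not depend on the iterate
        C = generate_model_tac(0.9, 0.3, 0.0, analytic_ref, schedule.mid_times)
        res = imrtm(TAC(C, schedule), ref_tac, tD=36.0, n_iter=5)
        assert res.k2a_pre == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.iterates[1], res.iterates[2], atol=1e-12)

    def test_release_tac_fluctuation_below_1pct_by_iter_10(self, sim_tacs):
        res = imrtm(sim_tacs["rel400"], sim_tacs["ref"], tD=36.0, n_iter=12,
                    truth_baseline=sim_tacs["baseline"].values)
        r = res.rmse_history
        fluct = np.abs(np.diff(r)) / r[:-1] * 100
        assert fluct[9] < 1.0

    def test_limit_matches_mrtm_fit_of_truth_baseline(self, sim_tacs):
        res = imrtm(sim_tacs["rel400"], sim_tacs["ref"], tD=36.0, n_iter=40)
        target = fit_mrtm(sim_tacs["baseline"], sim_tacs["ref"], window=(0.0, 36.0)).fitted
        rel_rmse = np.sqrt(np.mean((res.baseline - target) ** 2)) / np.mean(sim_tacs["baseline"].values)
        assert rel_rmse < 0.005

    def test_contraction_of_successive_iterates(self, sim_tacs):
        res = imrtm(sim_tacs["rel400"], sim_tacs["ref"], tD=36.0, n_iter=15)
        sup = [np.max(np.abs(b - a)) for a, b in zip(res.iterates[1:], res.iterates[2:])]
        ratios = np.array(sup[1:]) / np.array(sup[:-1])
        # geometric decay once the Volterra-series transient has passed
        assert np.all(ratios[3:] < 1.0)

    def test_batch_matches_single(self, schedule, sim_tacs):
        from rsdpet.kinetics import batch_imrtm

        Y = np.stack([sim_tacs["rel400"].values, sim_tacs["rel100"].values])
        out = batch_imrtm(Y, sim_tacs["ref"].values, schedule, 36.0, n_iter=10)
        single = imrtm(sim_tacs["rel400"], sim_tacs["ref"], tD=36.0, n_iter=10)
        assert np.allclose(out[0], single.baseline, atol=1e-9)


class TestBatchMRTM:
    def test_matches_single_fit_with_window(self, schedule, analytic_ref, ref_tac):
        C1 = generate_model_tac(0.9, 0.3, 0.12, analytic_ref, schedule.mid_times)
        C2 = generate_model_tac(1.05, 0.22, 0.06, analytic_ref, schedule.mid_times)
        coef, wrss, fitted = batch_mrtm(np.stack([C1, C2]), analytic_ref, schedule, window=(0.0, 36.0))
        for i, C in enumerate((C1, C2)):
            single = fit_mrtm(TAC(C, schedule), ref_tac, window=(0.0, 36.0))
            assert np.allclose(coef[i], (single.R1, single.k2, single.k2a), atol=1e-9)
            assert np.allclose(fitted[i], single.fitted, atol=1e-9)
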