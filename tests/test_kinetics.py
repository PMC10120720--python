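import math

import numpy as np
import pytest

from retinoflux import (
    KineticParams,
    Timecourse,
    compare_models,
    fit_accumulation,
    free_contribution_fraction,
    lag_time,
    predict_biphasic,
    predict_monophasic,
)


class TestPredictMonophasic:
    def test_zero_at_t0(self):
        p = KineticParams(kp=90, k1=0.02)
        assert predict_monophasic(p, 2.0, 0.0) == 0.0

    def test_asymptote(self):
        p = KineticParams(kp=90, k1=0.02)
        assert predict_monophasic(p, 2.0, 1e7) == pytest.approx(180.0, rel=1e-9)

    def test_hand_evaluation(self):
        # 0.4 * 90 * (1 - e^-1), frozen
        p = KineticParams(kp=90, k1=0.02)
        assert predict_monophasic(p, 0.4, 50.0) == pytest.approx(
            22.756340117828074, rel=1e-12
        )

    def test_vectorised(self):
        p = KineticParams(kp=90, k1=0.02)
        out = predict_monophasic(p, 0.4, [0.0, 50.0])
        assert out.shape == (2,)
        assert out[0] == 0.0


class TestLagTime:
    def test_zero_threshold(self):
        p = KineticParams(kp=90, k1=0.02, ccell_star=0.0)
        assert lag_time(p, 2.0) == 0.0

    def test_hand_evaluation(self):
        # -ln(1 - 36/180) / 0.02, frozen
        p = KineticParams(kp=90, k1=0.02, ccell_star=36.0)
        assert lag_time(p, 2.0) == pytest.approx(11.157177565710485, rel=1e-12)

    def test_never_branch(self):
        p = KineticParams(kp=90, k1=0.02, ccell_star=36.0)
        assert math.isinf(lag_time(p, 0.1))  # plateau 9 uM < threshold
        assert math.isinf(lag_time(p, 0.4))  # plateau exactly at threshold


class TestPredictBiphasic:
    def test_reduces_to_monophasic(self):
        p = KineticParams(kp=90, k1=0.02, kp_star=0.0)
        t = np.linspace(0, 120, 25)
        np.testing.assert_allclose(
            predict_biphasic(p, 2.0, t), predict_monophasic(p, 2.0, t), rtol=1e-14
        )

    def test_continuity_at_trigger(self):
        p = KineticParams(kp=90, k1=0.02, kp_star=70, k1_star=0.01, ccell_star=36)
        tlag = lag_time(p, 2.0)
        eps = 1e-9
        left = predict_biphasic(p, 2.0, tlag - eps)
        right = predict_biphasic(p, 2.0, tlag + eps)
        at = predict_biphasic(p, 2.0, tlag)
        assert right == pytest.approx(left, abs=1e-6)
        assert at == pytest.approx(predict_monophasic(p, 2.0, tlag), abs=1e-9)

    def test_hand_evaluation(self):
        # t = t_lag + 60: 180(1-e^{-0.02 t}) + 140(1-e^{-0.6}), frozen
        p = KineticParams(kp=90, k1=0.02, kp_star=70, k1_star=0.01, ccell_star=36)
        t = 11.157177565710485 + 60.0
        assert predict_biphasic(p, 2.0, t) == pytest.approx(
            199.7944044314792, rel=1e-10
        )

    def test_never_branch_stays_monophasic(self):
        p = KineticParams(kp=90, k1=0.02, kp_star=70, k1_star=0.01, ccell_star=36)
        t = np.linspace(0, 120, 25)
        np.testing.assert_allclose(
            predict_biphasic(p, 0.1, t),
            predict_monophasic(KineticParams(kp=90, k1=0.02), 0.1, t),
            rtol=1e-14,
        )

    def test_dominates_monophasic_and_monotone(self, study_params):
        t = np.linspace(0, 120, 241)
        for cf in (0.1, 0.4, 2.0):
            bi = predict_biphasic(study_params, cf, t)
            mono = predict_monophasic(study_params, cf, t)
            assert np.all(bi >= mono - 1e-12)
            assert np.all(np.diff(bi) >= -1e-12)

    def test_scale_invariance_before_trigger(self, study_params):
        # normalized curves at different cf coincide before the earliest lag
        tlag = lag_time(study_params, 2.0)
        t = np.linspace(0, tlag * 0.999, 50)
        norm = [predict_biphasic(study_params, cf, t) / cf for cf in (0.5, 1.0, 2.0)]
        for a in norm[1:]:
            assert np.max(np.abs(a - norm[0])) < 1e-9


class TestFitAccumulation:
    def test_monophasic_recovery_noiseless(self, five_min_grid):
        true = KineticParams(kp=90, k1=0.02)
        tc = Timecourse(cf=0.4, times=five_min_grid,
                        ccell=predict_monophasic(true, 0.4, five_min_grid))
        fit = fit_accumulation(tc, "monophasic", seed=0)
        assert fit.params.kp == pytest.approx(90.0, rel=1e-3)
        assert fit.params.k1 == pytest.approx(0.02, rel=1e-3)
        assert fit.sse < 1e-12

    def test_biphasic_recovery_noiseless(self, noiseless_timecourses, study_params):
        fit = fit_accumulation(noiseless_timecourses, "biphasic", seed=0)
        assert fit.params.kp == pytest.approx(study_params.kp, rel=0.01)
        assert fit.params.k1 == pytest.approx(study_params.k1, rel=0.01)
        assert fit.params.kp_star == pytest.approx(study_params.kp_star, rel=0.01)
        assert fit.params.k1_star == pytest.approx(study_params.k1_star, rel=0.01)
        assert fit.params.ccell_star == pytest.approx(study_params.ccell_star, rel=0.01)

    def test_determinism(self, noiseless_timecourses):
        f1 = fit_accumulation(noiseless_timecourses, "biphasic", seed=7)
        f2 = fit_accumulation(noiseless_timecourses, "biphasic", seed=7)
        assert f1.params == f2.params
        assert f1.sse == f2.sse

    def test_too_few_observations(self):
        tc = Timecourse(cf=1.0, times=[0.0, 10.0], ccell=[0.0, 1.0])
        with pytest.raises(ValueError):
            fit_accumulation(tc, "biphasic")

    def test_stderr_reported(self, noiseless_timecourses):
        rng = np.random.default_rng(0)
        noisy = [
            Timecourse(cf=tc.cf, times=tc.times,
                       ccell=tc.ccell * (1 + 0.05 * rng.standard_normal(tc.ccell.shape)))
            for tc in noiseless_timecourses
        ]
        fit = fit_accumulation(noisy, "biphasic", seed=0, n_starts=3)
        assert set(fit.stderr) == {"kp", "k1", "kp_star", "k1_star", "ccell_star"}
        assert all(v >= 0 for v in fit.stderr.values())


class TestCompareModels:
    def test_identical_sse_not_preferred(self, noiseless_timecourses):
        mono = fit_accumulation(noiseless_timecourses, "monophasic", seed=0)
        # fabricate a biphasic result with the same sse
        bi = fit_accumulation(noiseless_timecourses, "biphasic", seed=0)
        bi.sse = mono.sse
        cmp_res = compare_models(mono, bi)
        assert cmp_res.f_statistic == 0.0
        assert cmp_res.preferred == "monophasic"

    def test_biphasic_data_prefers_biphasic(self, noiseless_timecourses):
        rng = np.random.default_rng(123)
        noisy = [
            Timecourse(cf=tc.cf, times=tc.times,
                       ccell=np.maximum(
                           tc.ccell * (1 + 0.05 * rng.standard_normal(tc.ccell.shape)), 0))
            for tc in noiseless_timecourses
        ]
        mono = fit_accumulation(noisy, "monophasic", seed=0, n_starts=3)
        bi = fit_accumulation(noisy, "biphasic", seed=0, n_starts=3)
        cmp_res = compare_models(mono, bi)
        assert cmp_res.preferred == "biphasic"
        assert cmp_res.p_value < 0.001
        assert cmp_res.delta_aic < 0

    def test_non_nested_rejected(self, noiseless_timecourses):
        mono = fit_accumulation(noiseless_timecourses, "monophasic", seed=0)
        with pytest.raises(ValueError):
            compare_models(mono, mono)


class TestFreeContribution:
    def test_identical_curves(self, five_min_grid):
        c = np.linspace(1, 50, five_min_grid.size)
        a = Timecourse(cf=0.4, times=five_min_grid, ccell=c)
        b = Timecourse(cf=2.0, times=five_min_grid, ccell=c)
        t, frac = free_contribution_fraction(a, b)
        np.testing.assert_allclose(frac, 100.0)

    def test_half_curve(self, five_min_grid):
        c = np.linspace(1, 50, five_min_grid.size)
        a = Timecourse(cf=0.4, times=five_min_grid, ccell=0.5 * c)
        b = Timecourse(cf=2.0, times=five_min_grid, ccell=c)
        _, frac = free_contribution_fraction(a, b)
        np.testing.assert_allclose(frac, 50.0)

    def test_analytic_ratio(self, five_min_grid):
        # hand-built biphasic-style pair with a known ratio trajectory
        t = five_min_grid
        free_c = 40.0 * (1 - np.exp(-0.03 * t))
        bound_c = 90.0 * (1 - np.exp(-0.02 * t))
        a = Timecourse(cf=0.4, times=t, ccell=free_c)
        b = Timecourse(cf=2.0, times=t, ccell=bound_c)
        _, frac = free_contribution_fraction(a, b, cap=False)
        np.testing.assert_allclose(frac, 100.0 * free_c / bound_c, rtol=1e-9)

    def test_zero_denominator_missing(self):
        t = np.array([0.0, 10.0, 20.0])
        a = Timecourse(cf=0.4, times=t, ccell=[0.0, 1.0, 2.0])
        b = Timecourse(cf=2.0, times=t, ccell=[0.0, 2.0, 4.0])
        _, frac = free_contribution_fraction(a, b)
        assert math.isnan(frac[0])
        np.testing.assert_allclose(frac[1:], 50.0)

    def test_interpolation_to_coarser_grid(self):
        fine = np.arange(0.0, 121.0, 5.0)
        coarse = np.arange(0.0, 121.0, 15.0)
        a = Timecourse(cf=0.4, times=fine, ccell=2.0 * fine + 1.0)
        b = Timecourse(cf=2.0, times=coarse, ccell=4.0 * coarse + 2.0)
        t, frac = free_contribution_fraction(a, b)
        assert t.size == coarse.size
        np.testing.assert_allclose(frac, 50.0, rtol=1e-12)

    def test_disjoint_ranges_raise(self):
        a = Timecourse(cf=0.4, times=[0.0, 10.0], ccell=[0.0, 1.0])
        b = Timecourse(cf=2.0, times=[20.0, 30.0], ccell=[1.0, 2.0])
        with pytest.raises(ValueError):
            free_contribution_fraction(a, b)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        KineticParams(kp=-1, k1=0.02)
    with pytest.raises(ValueError):
        Timecourse(cf=0.0, times=[0, 5], ccell=[0, 1])
    with pytest.raises(ValueError):
        Timecourse(cf=1.0, times=[5, 5], ccell=[0, 1])
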