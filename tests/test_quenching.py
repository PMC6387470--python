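"""Inner-filter correction, Stern-Volmer and double-log binding analysis."""

import math

import numpy as np
import pytest

from albuminbind import (
    Constants,
    QuenchFit,
    QuenchTitration,
    SynthConfig,
    classify_quenching,
    correct_inner_filter,
    fit_double_log,
    fit_stern_volmer,
    gen_quench_titration,
)
from albuminbind.exceptions import (
    ExcludedPointWarning,
    FitError,
    ParameterError,
    ValidationError,
)


class TestInnerFilter:
    def test_zero_absorbance_identity(self):
        assert correct_inner_filter(1000.0, 0.0, 0.0) == 1000.0

    def test_direct_evaluation(self):
        # F * exp((A_ex + A_em)/2) with A_ex=0.10, A_em=0.05
        assert correct_inner_filter(1000.0, 0.10, 0.05) == pytest.approx(
            1000.0 * math.exp(0.075), rel=1e-12
        )
        assert correct_inner_filter(1000.0, 0.10, 0.05) == pytest.approx(1077.88, abs=0.01)

    def test_doubling_absorbances_squares_factor(self):
        f1 = correct_inner_filter(1.0, 0.10, 0.05)
        f2 = correct_inner_filter(1.0, 0.20, 0.10)
        assert f2 == pytest.approx(f1**2, rel=1e-12)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ParameterError):
            correct_inner_filter(1000.0, -0.1, 0.0)


class TestTitrationValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(quencher_M=[1e-6, 2e-6, 3e-6, 4e-6], F_obs=[4, 3, 2, 1]),  # no zero point
            dict(quencher_M=[0, 2e-6, 1e-6, 4e-6], F_obs=[4, 3, 2, 1]),  # not increasing
            dict(quencher_M=[0, 1e-6, 2e-6, 3e-6], F_obs=[4, 3, 0, 1]),  # non-positive F
            dict(quencher_M=[0, 1e-6, 2e-6], F_obs=[3, 2, 1]),  # too short
        ],
    )
    def test_invariants(self, kwargs):
        with pytest.raises(ValidationError):
            QuenchTitration(temperature_K=298.15, **kwargs)

    def test_from_csv_averages_replicates(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "quencher_M,rep1,rep2\n0,100,102\n1e-5,90,92\n2e-5,80,82\n3e-5,70,72\n"
        )
        t = QuenchTitration.from_csv(p, temperature_C=25.0)
        assert t.F_obs.tolist() == [101.0, 91.0, 81.0, 71.0]
        assert t.temperature_K == pytest.approx(298.15)


class TestSternVolmer:
    def test_noise_free_recovery_six_digits(self):
        t = gen_quench_titration(K_b=1.7e4, cfg=SynthConfig(0))
        res = fit_stern_volmer(t)
        assert res.K_SV == pytest.approx(1.7e4, rel=1e-6)
        assert res.intercept == pytest.approx(1.0, rel=1e-9)
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_kq_is_ksv_over_tau0(self):
        # audited identity across seeds and noise
        c = Constants()
        for seed in range(5):
            t = gen_quench_titration(cfg=SynthConfig(seed, "lognormal_multiplicative", 0.01))
            res = fit_stern_volmer(t, c)
            assert res.k_q == res.K_SV / c.tau0_s

    def test_kq_magnitude_static_regime(self):
        # K_SV = 1.0e4 M^-1 with tau0 = 5.78 ns gives k_q ~ 1.7e12 M^-1 s^-1,
        # far above the diffusion-controlled ceiling
        t = gen_quench_titration(K_b=1.0e4, cfg=SynthConfig(0))
        res = fit_stern_volmer(t)
        assert round(res.k_q / 1e11) / 10 == 1.7  # 1.7 x 10^12 after rounding

    def test_no_quenching_gives_zero_slope(self):
        t = QuenchTitration(298.15, [0, 1e-5, 2e-5, 3e-5, 4e-5], [100.0] * 5)
        res = fit_stern_volmer(t)
        assert res.K_SV == pytest.approx(0.0, abs=1e-9)

    def test_too_few_nonzero_points(self):
        with pytest.raises(ValidationError):
            QuenchTitration(298.15, [0, 1e-5, 2e-5], [100, 90, 80])


class TestDoubleLog:
    def test_exact_recovery(self):
        t = gen_quench_titration(K_b=1.6e4, n_stoich=1.0, cfg=SynthConfig(0))
        res = fit_double_log(t)
        assert res.K_b == pytest.approx(1.6e4, rel=1e-9)
        assert res.n_stoich == pytest.approx(1.0, abs=1e-6)

    def test_n_equals_one_matches_stern_volmer(self):
        # for 1:1 stoichiometry the double-log K_b equals K_SV
        t = gen_quench_titration(K_b=1.6e4, n_stoich=1.0, cfg=SynthConfig(0))
        sv = fit_stern_volmer(t)
        dl = fit_double_log(t)
        assert dl.K_b == pytest.approx(sv.K_SV, rel=0.01)

    def test_monte_carlo_kb_recovery_within_5pct(self):
        # 500 replicates at 1% multiplicative noise; median relative error < 5%
        errors = []
        for seed in range(500):
            t = gen_quench_titration(
                K_b=1.6e4, cfg=SynthConfig(seed, "lognormal_multiplicative", 0.01)
            )
            errors.append(abs(fit_double_log(t).K_b - 1.6e4) / 1.6e4)
        assert np.median(errors) < 0.05

    def test_unquenched_points_excluded_with_warning(self):
        F = np.array([100.0, 101.0, 80.0, 70.0, 60.0, 50.0])
        t = QuenchTitration(298.15, [0, 1e-5, 2e-5, 3e-5, 4e-5, 5e-5], F)
        with pytest.warns(ExcludedPointWarning):
            res = fit_double_log(t)
        assert res.n_excluded == 1
        assert res.nobs == 4

    def test_too_few_usable_points(self):
        F = np.array([100.0, 101.0, 102.0, 103.0, 60.0, 50.0])
        t = QuenchTitration(298.15, [0, 1e-5, 2e-5, 3e-5, 4e-5, 5e-5], F)
        with pytest.warns(ExcludedPointWarning), pytest.raises(FitError):
            fit_double_log(t)


class TestMechanismClassification:
    def _fits(self, ksv_by_T, temps_K, tau0=5.78e-9, kq=None):
        from types import SimpleNamespace

        out = []
        for T, ksv in zip(temps_K, ksv_by_T):
            out.append(
                SimpleNamespace(temperature_K=T, K_SV=ksv, k_q=kq if kq else ksv / tau0)
            )
        return out

    def test_static_decreasing_ksv_high_kq(self):
        fits = self._fits([1.7e4, 1.3e4, 1.0e4], [298.15, 303.15, 310.15])
        assert classify_quenching(fits).label == "static"

    def test_dynamic_increasing_ksv_low_kq(self):
        fits = self._fits([10, 20, 30], [298.15, 303.15, 310.15], kq=5e9)
        assert classify_quenching(fits).label == "dynamic"

    def test_non_monotone_is_indeterminate(self):
        fits = self._fits([1.7e4, 1.0e4, 1.3e4], [298.15, 303.15, 310.15])
        mech = classify_quenching(fits)
        assert mech.label == "indeterminate"
        assert mech.reasons

    def test_unsorted_temperatures_rejected(self):
        fits = self._fits([1.7e4, 1.3e4], [310.15, 298.15])
        with pytest.raises(ParameterError):
            classify_quenching(fits)

    def test_end_to_end_static_call_on_synthetic_series(self):
        fits = [
            QuenchFit.from_titration(
                gen_quench_titration(K_b=kb, temperature_C=tc, cfg=SynthConfig(0))
            )
            for kb, tc in [(1.7e4, 25.0), (1.3e4, 30.0), (1.0e4, 37.0)]
        ]
        assert classify_quenching(fits).label == "static"
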