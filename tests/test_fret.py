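"""Förster transfer: overlap integral, R0, efficiency/distance inversion."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from albuminbind import (
    Constants,
    FretAnalysis,
    Spectrum,
    check_fret_validity,
    distance_from_efficiency,
    efficiency_from_distance,
    efficiency_from_intensity,
    forster_radius,
    overlap_integral,
)
from albuminbind.fret import FORSTER_PREFACTOR_CM6, efficiency_consistency
from albuminbind.exceptions import ConsistencyWarning, DomainError, RangeWarning


class TestOverlapIntegral:
    def test_constant_extinction_gaussian_moment(self, gaussian_spectrum_factory):
        # With eps(l) = const, J = eps * E[l^4] under the emission-normalised
        # weight; for a Gaussian E[x^4] = mu^4 + 6 mu^2 s^2 + 3 s^4.
        donor = gaussian_spectrum_factory(center=340.0, sd=15.0)
        grid = donor.wavelength_nm
        eps = 1000.0
        acceptor = Spectrum(grid, np.full(grid.size, eps), signal_kind="molar_extinction_M1cm1")
        mu, s = 340.0e-7, 15.0e-7
        analytic = eps * (mu**4 + 6 * mu**2 * s**2 + 3 * s**4)
        assert overlap_integral(donor, acceptor) == pytest.approx(analytic, rel=1e-3)

    def test_zero_extinction_gives_zero(self, gaussian_spectrum_factory):
        donor = gaussian_spectrum_factory()
        acceptor = Spectrum(donor.wavelength_nm, np.zeros(len(donor)),
                            signal_kind="molar_extinction_M1cm1")
        assert overlap_integral(donor, acceptor) == 0.0

    def test_no_overlap_warns_and_returns_zero(self, gaussian_spectrum_factory):
        donor = gaussian_spectrum_factory(grid=np.arange(300.0, 401.0))
        acceptor = gaussian_spectrum_factory(
            center=500.0, grid=np.arange(450.0, 551.0), kind="molar_extinction_M1cm1"
        )
        with pytest.warns(RangeWarning):
            assert overlap_integral(donor, acceptor) == 0.0

    def test_donor_amplitude_invariance(self, band_spectra):
        donor, acceptor = band_spectra
        j1 = overlap_integral(donor, acceptor)
        scaled = Spectrum(donor.wavelength_nm, 10.0 * donor.signal,
                          signal_kind=donor.signal_kind)
        j2 = overlap_integral(scaled, acceptor)
        assert abs(j2 - j1) / j1 < 1e-12

    def test_grid_refinement_invariance(self, gaussian_spectrum_factory):
        coarse_d = gaussian_spectrum_factory(grid=np.arange(280.0, 421.0, 1.0))
        coarse_a = gaussian_spectrum_factory(center=335.0, sd=25.0, amplitude=4000.0,
                                             grid=np.arange(280.0, 421.0, 1.0),
                                             kind="molar_extinction_M1cm1")
        fine_d = gaussian_spectrum_factory(grid=np.arange(280.0, 420.01, 0.1))
        fine_a = gaussian_spectrum_factory(center=335.0, sd=25.0, amplitude=4000.0,
                                           grid=np.arange(280.0, 420.01, 0.1),
                                           kind="molar_extinction_M1cm1")
        j_coarse = overlap_integral(coarse_d, coarse_a)
        j_fine = overlap_integral(fine_d, fine_a)
        assert abs(j_fine - j_coarse) / j_fine < 1e-3

    def test_zero_donor_signal_rejected(self):
        grid = np.arange(300.0, 304.0)
        donor = Spectrum(grid, np.zeros(grid.size), signal_kind="fluorescence_au")
        acceptor = Spectrum(grid, np.ones(grid.size), signal_kind="molar_extinction_M1cm1")
        with pytest.raises(DomainError):
            overlap_integral(donor, acceptor)


class TestForsterRadius:
    def test_zero_overlap_degenerate(self):
        assert forster_radius(0.0) == 0.0

    def test_default_constants_give_about_2nm(self):
        # direct evaluation with kappa2=2/3, n=1.336, phi=0.118
        j = 3.08e-15
        expected = (FORSTER_PREFACTOR_CM6 * (2 / 3) * 1.336**-4 * 0.118 * j) ** (1 / 6) * 1e7
        r0 = forster_radius(j)
        assert r0 == pytest.approx(expected, rel=1e-12)
        assert r0 == pytest.approx(2.0, abs=0.05)

    def test_sixth_root_scaling_in_quantum_yield(self):
        j = 3.08e-15
        r0 = forster_radius(j, Constants(quantum_yield=0.118))
        r0_double = forster_radius(j, Constants(quantum_yield=0.236))
        assert r0_double / r0 == pytest.approx(2 ** (1 / 6), rel=1e-12)

    def test_monotonicity_in_each_factor(self):
        base = Constants()
        j = 3.0e-15
        assert forster_radius(j, Constants(kappa2=1.0)) > forster_radius(j, base)
        assert forster_radius(j, Constants(quantum_yield=0.2)) > forster_radius(j, base)
        assert forster_radius(2 * j, base) > forster_radius(j, base)
        assert forster_radius(j, Constants(refractive_index=1.5)) < forster_radius(j, base)


class TestEfficiencyDistance:
    def test_intensity_route(self):
        assert efficiency_from_intensity(100.0, 100.0) == 0.0
        assert efficiency_from_intensity(50.0, 100.0) == 0.5
        # measured intensity pair: quenched 1829 vs unquenched 2546
        assert efficiency_from_intensity(1829.0, 2546.0) == pytest.approx(0.282, abs=5e-4)
        with pytest.raises(DomainError):
            efficiency_from_intensity(110.0, 100.0)

    def test_distance_route(self):
        assert efficiency_from_distance(2.0, 2.0) == 0.5
        assert efficiency_from_distance(2.18, 2.34) == pytest.approx(0.395, abs=5e-4)
        assert efficiency_from_distance(2.0, 1e6) < 1e-12

    def test_inversion(self):
        assert distance_from_efficiency(0.5, 3.1) == pytest.approx(3.1, rel=1e-12)
        assert distance_from_efficiency(0.39, 2.18) == pytest.approx(2.35, abs=0.01)
        with pytest.raises(DomainError):
            distance_from_efficiency(1.0, 2.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        E=st.floats(min_value=1e-6, max_value=1.0 - 1e-6),
        R0=st.floats(min_value=0.5, max_value=10.0),
    )
    def test_round_trip_identity(self, E, R0):
        r = distance_from_efficiency(E, R0)
        assert abs(efficiency_from_distance(R0, r) - E) < 1e-10

    def test_round_trip_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            R0 = rng.uniform(1.0, 8.0)
            r = rng.uniform(0.5, 12.0)
            E = efficiency_from_distance(R0, r)
            assert abs(distance_from_efficiency(E, R0) - r) < 1e-10 * max(1.0, r)


class TestValidity:
    def test_reported_geometry_is_valid(self):
        v = check_fret_validity(2.18, 2.34)
        assert v.ratio_ok and v.scale_ok and v.ok

    def test_ratio_criterion(self):
        assert not check_fret_validity(2.0, 4.0).ratio_ok

    def test_scale_criterion(self):
        assert not check_fret_validity(2.0, 1.0).scale_ok

    def test_route_disagreement_flagged(self):
        # intensity-derived E = 0.282 vs the E implied by R0 = 2.18, r = 2.34
        with pytest.warns(ConsistencyWarning):
            e_dist, agree = efficiency_consistency(0.282, 2.18, 2.34)
        assert not agree
        assert e_dist == pytest.approx(0.395, abs=1e-3)


class TestFretAnalysis:
    def test_end_to_end_on_synthetic_bands(self, band_spectra):
        donor, acceptor = band_spectra
        res = FretAnalysis(donor, acceptor, F0=2546.0, F=1829.0).run()
        assert res.J_cm3_M1 > 0
        assert 1.0 < res.R0_nm < 4.0
        assert res.E == pytest.approx(1 - 1829.0 / 2546.0, rel=1e-12)
        # the distance must invert the efficiency exactly
        assert efficiency_from_distance(res.R0_nm, res.r_nm) == pytest.approx(res.E, abs=1e-12)
        assert dataclasses.asdict(res.validity).keys() == {"ratio_ok", "scale_ok", "ok"}
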