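"""Core spectral container: parsing, round-trip I/O, interpolation, derivatives."""

import math

import numpy as np
import pytest

from albuminbind import (
    Spectrum,
    difference_spectrum,
    interp_to_grid,
    read_spectrum,
    second_derivative,
    write_spectrum,
)
from albuminbind.exceptions import (
    GridRangeError,
    ParameterError,
    SpectrumParseError,
    ValidationError,
)


def _write(tmp_path, text, name="s.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadWrite:
    def test_direct_parse(self, tmp_path):
        s = read_spectrum(_write(tmp_path, "280,0.29\n281,0.30\n282,0.31"))
        assert len(s) == 3
        assert s.wavelength_nm.tolist() == [280.0, 281.0, 282.0]
        assert s.signal.tolist() == [0.29, 0.30, 0.31]

    @pytest.mark.parametrize("sep", [",", "\t", "  "])
    def test_delimiters_autodetected(self, tmp_path, sep):
        s = read_spectrum(_write(tmp_path, f"# comment\n280{sep}0.1\n281{sep}0.2\n282{sep}0.3"))
        assert len(s) == 3

    def test_rows_sorted_by_wavelength(self, tmp_path):
        s = read_spectrum(_write(tmp_path, "282,0.3\n280,0.1\n281,0.2"))
        assert s.wavelength_nm.tolist() == [280.0, 281.0, 282.0]
        assert s.signal.tolist() == [0.1, 0.2, 0.3]

    def test_duplicate_wavelength_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            read_spectrum(_write(tmp_path, "280,0.1\n280,0.2\n282,0.3"))

    def test_malformed_row_names_line(self, tmp_path):
        with pytest.raises(SpectrumParseError, match="line 2"):
            read_spectrum(_write(tmp_path, "280,0.1\n281,abc\n282,0.3"))

    def test_too_few_rows(self, tmp_path):
        with pytest.raises(ValidationError):
            read_spectrum(_write(tmp_path, "280,0.1\n281,0.2"))

    def test_round_trip_bit_identical(self, tmp_path, gaussian_spectrum_factory):
        s = gaussian_spectrum_factory(center=280.0, sd=8.0, amplitude=0.7, kind="absorbance")
        p = tmp_path / "band.csv"
        write_spectrum(s, p)
        back = read_spectrum(p, kind="absorbance")
        assert np.array_equal(back.wavelength_nm, s.wavelength_nm)
        assert np.array_equal(back.signal, s.signal)


class TestInvariants:
    def test_nonnegative_kinds_enforced(self):
        with pytest.raises(ValidationError):
            Spectrum([280, 281, 282], [0.1, -0.2, 0.3], signal_kind="absorbance")

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            Spectrum([280, 281, 282], [0.1, np.nan, 0.3], signal_kind="fluorescence_au")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            Spectrum([280, 281, 282], [1, 2, 3], signal_kind="transmittance")


class TestInterp:
    def test_identity_on_own_grid(self, gaussian_spectrum_factory):
        s = gaussian_spectrum_factory()
        out = interp_to_grid(s, s.wavelength_nm)
        assert np.array_equal(out.signal, s.signal)

    def test_linear_midpoints(self):
        s = Spectrum([300.0, 302.0, 304.0], [0.0, 2.0, 4.0], signal_kind="fluorescence_au")
        assert interp_to_grid(s, [301.0, 302.0, 303.0]).signal.tolist() == [1.0, 2.0, 3.0]

    def test_gaussian_refinement_accuracy(self, gaussian_spectrum_factory):
        s = gaussian_spectrum_factory(center=340.0, sd=15.0)
        fine = np.arange(300.0, 380.0, 0.1)
        out = interp_to_grid(s, fine)
        analytic = np.exp(-0.5 * ((fine - 340.0) / 15.0) ** 2)
        assert np.max(np.abs(out.signal - analytic)) < 1e-3  # peak height is 1

    def test_extrapolation_rejected(self, gaussian_spectrum_factory):
        s = gaussian_spectrum_factory()
        with pytest.raises(GridRangeError):
            interp_to_grid(s, [200.0, 300.0, 400.0])


class TestSecondDerivative:
    def test_line_is_flat(self):
        grid = np.arange(250.0, 300.0)
        s = Spectrum(grid, 0.01 * grid + 3.0, signal_kind="fluorescence_au")
        assert np.max(np.abs(second_derivative(s).signal)) < 1e-10

    def test_parabola_constant(self):
        grid = np.arange(250.0, 300.0)
        a = 0.05
        s = Spectrum(grid, a * grid**2, signal_kind="fluorescence_au")
        d2 = second_derivative(s).signal
        assert np.allclose(d2, 2 * a, rtol=1e-8)

    def test_two_band_minima_at_centers(self):
        # Overlapping aromatic-like bands; d2 minima locate the centers.
        grid = np.arange(240.0, 310.0, 0.5)
        sig = np.exp(-0.5 * ((grid - 260.0) / 6.0) ** 2) + np.exp(-0.5 * ((grid - 280.0) / 6.0) ** 2)
        d2 = second_derivative(Spectrum(grid, sig, signal_kind="absorbance"), window=9, polyorder=3)
        for center in (260.0, 280.0):
            region = (grid > center - 5) & (grid < center + 5)
            found = grid[region][np.argmin(d2.signal[region])]
            assert abs(found - center) <= 1.0

    @pytest.mark.parametrize("window,polyorder", [(6, 3), (5, 4), (501, 3)])
    def test_bad_parameters(self, gaussian_spectrum_factory, window, polyorder):
        with pytest.raises(ParameterError):
            second_derivative(gaussian_spectrum_factory(), window=window, polyorder=polyorder)

    def test_nonuniform_grid_rejected(self):
        s = Spectrum([250.0, 251.0, 253.0, 258.0, 260.0, 261.0, 262.0],
                     [1, 2, 3, 4, 3, 2, 1], signal_kind="fluorescence_au")
        with pytest.raises(ParameterError):
            second_derivative(s, window=5)


class TestDifference:
    def test_identity_flags_none(self, gaussian_spectrum_factory):
        s = gaussian_spectrum_factory(center=280.0, kind="absorbance")
        d = difference_spectrum(s, s, window_nm=(270.0, 290.0))
        assert np.all(d.spectrum.signal == 0)
        assert d.chromism == "none"

    def test_scaled_band_is_hyperchromic(self, gaussian_spectrum_factory):
        a = gaussian_spectrum_factory(center=280.0, amplitude=1.0, kind="absorbance")
        b = gaussian_spectrum_factory(center=280.0, amplitude=1.2, kind="absorbance")
        d = difference_spectrum(b, a, window_nm=(270.0, 290.0))
        assert d.chromism == "hyperchromic"
        assert difference_spectrum(a, b, window_nm=(270.0, 290.0)).chromism == "hypochromic"

    def test_peak_increase_located_at_band_center(self, gaussian_spectrum_factory):
        free = gaussian_spectrum_factory(center=280.0, sd=10.0, amplitude=0.50, kind="absorbance")
        bound = gaussian_spectrum_factory(center=280.0, sd=10.0, amplitude=0.525, kind="absorbance")
        d = difference_spectrum(bound, free)
        assert abs(d.wavelength_at_max_nm - 280.0) <= 1.0
        assert d.max_abs_delta == pytest.approx(0.025, rel=1e-9)

    def test_disjoint_ranges_rejected(self):
        a = Spectrum([250, 251, 252], [1, 2, 3], signal_kind="absorbance")
        b = Spectrum([300, 301, 302], [1, 2, 3], signal_kind="absorbance")
        with pytest.raises(GridRangeError):
            difference_spectrum(a, b)
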