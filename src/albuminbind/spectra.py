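"""Spectral data container, plain-text I/O, interpolation and derivatives.

A :class:`Spectrum` is a sampled optical signal on a strictly increasing
wavelength grid in nm — absorbance, fluorescence (a.u.), ellipticity (mdeg)
or molar extinction (M^-1 cm^-1). Files are two-column delimited text
(wavelength, signal) with ``#`` comments; comma, tab or whitespace
separated, decimal point only.

Derivative spectra use the Savitzky-Golay convention (local polynomial
smoothing), the standard approach in derivative UV spectroscopy where the
second derivative resolves the overlapping Phe/Tyr/Trp aromatic bands near
260/270/280 nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import (
    GridRangeError,
    ParameterError,
    SpectrumParseError,
    ValidationError,
)

SIGNAL_KINDS = (
    "absorbance",
    "fluorescence_au",
    "ellipticity_mdeg",
    "molar_extinction_M1cm1",
    # signed arbitrary-unit kind for derivative/difference products, which
    # go negative even when the parent kind cannot
    "derived",
)
#: Kinds whose physical values cannot be negative.
NONNEGATIVE_KINDS = ("absorbance", "molar_extinction_M1cm1")


@dataclass(frozen=True)
class Spectrum:
    """A sampled optical signal on a strictly increasing nm grid."""

    wavelength_nm: np.ndarray
    signal: np.ndarray
    signal_kind: str = "absorbance"
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        sg = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "signal", sg)
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValidationError(
                f"signal_kind {self.signal_kind!r} not one of {SIGNAL_KINDS}"
            )
        if wl.ndim != 1 or sg.ndim != 1 or wl.shape != sg.shape:
            raise ValidationError("wavelength and signal must be 1-D arrays of equal length")
        if wl.size < 3:
            raise ValidationError(f"a spectrum needs at least 3 points, got {wl.size}")
        if np.isnan(wl).any() or np.isnan(sg).any():
            raise ValidationError("NaN values are not allowed in a spectrum")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelength grid must be strictly increasing (no duplicates)")
        if self.signal_kind in NONNEGATIVE_KINDS and np.any(sg < 0):
            raise ValidationError(f"{self.signal_kind} values must be >= 0")

    def __len__(self) -> int:
        return int(self.wavelength_nm.size)

    @property
    def wavelength_range(self) -> tuple[float, float]:
        return float(self.wavelength_nm[0]), float(self.wavelength_nm[-1])

    def interp_to(self, grid: Sequence[float]) -> "Spectrum":
        return interp_to_grid(self, grid)

    def second_derivative(self, window: int = 7, polyorder: int = 3) -> "Spectrum":
        return second_derivative(self, window=window, polyorder=polyorder)

    def to_csv(self, path: str | Path) -> None:
        write_spectrum(self, path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "absorbance", label: str | None = None) -> "Spectrum":
        return read_spectrum(path, kind=kind, label=label)


def _split_row(line: str) -> list[str]:
    if "," in line:
        return [p.strip() for p in line.split(",")]
    if "\t" in line:
        return [p.strip() for p in line.split("\t")]
    return line.split()


def read_spectrum(path: str | Path, kind: str = "absorbance", label: str | None = None) -> Spectrum:
    """Read a two-column (wavelength nm, signal) text file into a Spectrum.

    Comment lines start with ``#``; comma, tab or whitespace delimiters are
    auto-detected per line. Rows are sorted by wavelength; duplicate
    wavelengths are rejected.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text or text.startswith("#"):
                continue
            parts = _split_row(text)
            if len(parts) < 2:
                raise SpectrumParseError(f"{path.name}, line {lineno}: expected two columns, got {text!r}")
            try:
                wl, sg = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise SpectrumParseError(f"{path.name}, line {lineno}: non-numeric value in {text!r}") from exc
            rows.append((wl, sg))
    if len(rows) < 3:
        raise ValidationError(f"{path.name}: fewer than 3 usable rows ({len(rows)})")
    rows.sort(key=lambda r: r[0])
    wl = np.array([r[0] for r in rows])
    sg = np.array([r[1] for r in rows])
    return Spectrum(wl, sg, signal_kind=kind, label=label if label is not None else path.stem)


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a Spectrum as comma-separated text; round-trips losslessly."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# wavelength_nm,{s.signal_kind}\n")
        for wl, sg in zip(s.wavelength_nm, s.signal):
            # repr() of a Python float is the shortest digit string that
            # round-trips exactly, so read-after-write is bit-identical.
            fh.write(f"{float(wl)!r},{float(sg)!r}\n")


def interp_to_grid(s: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linear interpolation of a spectrum onto a new grid (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.wavelength_range
    if grid.size and (grid.min() < lo or grid.max() > hi):
        raise GridRangeError(
            f"requested grid [{grid.min()}, {grid.max()}] extends beyond spectrum range [{lo}, {hi}]"
        )
    values = np.interp(grid, s.wavelength_nm, s.signal)
    return replace(s, wavelength_nm=grid, signal=values)


def second_derivative(s: Spectrum, window: int = 7, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay smoothed d2(signal)/d(wavelength)2 on the input grid.

    Requires a uniformly spaced grid (the Savitzky-Golay kernel assumes it).
    """
    if window % 2 == 0:
        raise ParameterError(f"window must be odd, got {window}")
    if window < polyorder + 2:
        raise ParameterError(f"window ({window}) must be >= polyorder + 2 ({polyorder + 2})")
    if window > len(s):
        raise ParameterError(f"window ({window}) exceeds spectrum length ({len(s)})")
    steps = np.diff(s.wavelength_nm)
    delta = float(steps.mean())
    if not np.allclose(steps, delta, rtol=1e-6, atol=0.0):
        raise ParameterError("second_derivative requires a uniformly spaced wavelength grid")
    d2 = savgol_filter(s.signal, window_length=window, polyorder=polyorder, deriv=2, delta=delta)
    return Spectrum(s.wavelength_nm, d2, signal_kind="derived", label=f"d2({s.label})")


@dataclass(frozen=True)
class SpectralDifference:
    """Pointwise difference a - b with summary diagnostics.

    ``chromism`` reports the sign of the mean change of *a* relative to *b*
    in ``window_nm``: "hyperchromic" (intensity rise), "hypochromic"
    (intensity loss) or "none".
    """

    spectrum: Spectrum
    max_abs_delta: float
    wavelength_at_max_nm: float
    window_nm: tuple[float, float] | None
    mean_delta_in_window: float
    chromism: str


def difference_spectrum(
    a: Spectrum,
    b: Spectrum,
    window_nm: tuple[float, float] | None = None,
) -> SpectralDifference:
    """Compute a - b on a common grid and classify hyper/hypochromism.

    Spectra with different grids are interpolated onto the union of their
    sample points within the overlapping wavelength range.
    """
    if np.array_equal(a.wavelength_nm, b.wavelength_nm):
        grid = a.wavelength_nm
    else:
        lo = max(a.wavelength_nm[0], b.wavelength_nm[0])
        hi = min(a.wavelength_nm[-1], b.wavelength_nm[-1])
        if lo >= hi:
            raise GridRangeError("spectra have disjoint wavelength ranges")
        pts = np.union1d(a.wavelength_nm, b.wavelength_nm)
        grid = pts[(pts >= lo) & (pts <= hi)]
        if grid.size < 3:
            raise GridRangeError("overlapping range contains fewer than 3 grid points")
    da = np.interp(grid, a.wavelength_nm, a.signal)
    db = np.interp(grid, b.wavelength_nm, b.signal)
    delta = da - db
    imax = int(np.argmax(np.abs(delta)))
    if window_nm is None:
        win_mask = np.ones_like(grid, dtype=bool)
    else:
        wlo, whi = window_nm
        win_mask = (grid >= wlo) & (grid <= whi)
        if not win_mask.any():
            raise GridRangeError(f"window {window_nm} contains no grid points")
    mean_delta = float(delta[win_mask].mean())
    scale = max(1.0, float(np.max(np.abs(da))), float(np.max(np.abs(db))))
    tol = 1e-12 * scale
    if mean_delta > tol:
        chromism = "hyperchromic"
    elif mean_delta < -tol:
        chromism = "hypochromic"
    else:
        chromism = "none"
    diff = Spectrum(grid, delta, signal_kind="derived", label=f"{a.label} - {b.label}")
    return SpectralDifference(
        spectrum=diff,
        max_abs_delta=float(np.abs(delta[imax])),
        wavelength_at_max_nm=float(grid[imax]),
        window_nm=window_nm,
        mean_delta_in_window=mean_delta,
        chromism=chromism,
    )
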