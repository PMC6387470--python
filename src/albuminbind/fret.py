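"""Förster resonance energy transfer: overlap integral, R0, efficiency, distance.

The donor is the protein tryptophan emission band (a.u.); the acceptor is
the ligand absorption expressed as molar extinction (M^-1 cm^-1). The
spectral overlap integral

    J = Int F(l) e(l) l^4 dl / Int F(l) dl

is evaluated with the wavelength in cm so that the Förster relation

    R0^6 = 8.79e-25 k2 n^-4 phi J        (cm^6)

is dimensionally consistent and yields R0 in cm (returned in nm). The
transfer efficiency relates intensities and distance:

    E = 1 - F/F0 = R0^6 / (R0^6 + r^6)

FRET distance estimates are considered meaningful when r lies on the
2-8 nm scale and within 0.5 R0 < r < 1.5 R0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, Constants
from .exceptions import ConsistencyWarning, DomainError, RangeWarning, ValidationError
from .spectra import Spectrum

NM_TO_CM = 1e-7
#: Förster prefactor in cm^6 when J is in cm^3 M^-1 (kappa^2, n, phi dimensionless).
FORSTER_PREFACTOR_CM6 = 8.79e-25


def overlap_integral(donor_emission: Spectrum, acceptor_extinction: Spectrum) -> float:
    """Spectral overlap integral J in cm^3 M^-1 (trapezoidal rule).

    Both spectra are interpolated onto a common grid at the finer of the
    two native spacings; the acceptor extinction is taken as zero outside
    its measured range. J is independent of the donor amplitude scale.
    """
    d, a = donor_emission, acceptor_extinction
    lo = max(d.wavelength_nm[0], a.wavelength_nm[0])
    hi = min(d.wavelength_nm[-1], a.wavelength_nm[-1])
    denom = np.trapezoid(d.signal, d.wavelength_nm * NM_TO_CM)
    if denom <= 0:
        raise DomainError("donor emission integrates to zero; no donor signal")
    if lo >= hi:
        warnings.warn("donor and acceptor spectra do not overlap; J = 0", RangeWarning, stacklevel=2)
        return 0.0
    step = min(float(np.median(np.diff(d.wavelength_nm))), float(np.median(np.diff(a.wavelength_nm))))
    n_pts = max(int(np.ceil((hi - lo) / step)) + 1, 3)
    grid = np.linspace(lo, hi, n_pts)
    F = np.interp(grid, d.wavelength_nm, d.signal)
    eps = np.interp(grid, a.wavelength_nm, a.signal)
    lam_cm = grid * NM_TO_CM
    numer = np.trapezoid(F * eps * lam_cm**4, lam_cm)
    return float(numer / denom)


def forster_radius(J_cm3_M1: float, constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Critical transfer distance R0 in nm from the overlap integral."""
    if J_cm3_M1 < 0:
        raise DomainError("overlap integral J must be >= 0")
    r0_6 = (
        FORSTER_PREFACTOR_CM6
        * constants.kappa2
        * constants.refractive_index**-4
        * constants.quantum_yield
        * J_cm3_M1
    )
    return float(r0_6 ** (1.0 / 6.0) / NM_TO_CM)


def efficiency_from_intensity(F: float, F0: float) -> float:
    """E = 1 - F/F0 from quenched and unquenched donor intensities."""
    if not (0 < F <= F0):
        raise DomainError(f"require 0 < F <= F0, got F={F}, F0={F0}")
    return 1.0 - F / F0


def efficiency_from_distance(R0_nm: float, r_nm: float) -> float:
    """E = R0^6 / (R0^6 + r^6)."""
    if R0_nm <= 0 or r_nm <= 0:
        raise DomainError("R0 and r must be positive")
    return R0_nm**6 / (R0_nm**6 + r_nm**6)


def distance_from_efficiency(E: float, R0_nm: float) -> float:
    """Invert the efficiency-distance relation: r = R0 ((1-E)/E)^(1/6)."""
    if not (0 < E < 1):
        raise DomainError(f"E must lie strictly in (0, 1), got {E}")
    if R0_nm <= 0:
        raise DomainError("R0 must be positive")
    return R0_nm * ((1.0 - E) / E) ** (1.0 / 6.0)


@dataclass(frozen=True)
class FretValidity:
    """Criteria for a physically meaningful FRET distance estimate."""

    ratio_ok: bool  # 0.5 R0 < r < 1.5 R0
    scale_ok: bool  # 2 nm <= r <= 8 nm
    ok: bool


def check_fret_validity(R0_nm: float, r_nm: float, scale_nm: tuple[float, float] = (2.0, 8.0)) -> FretValidity:
    if R0_nm <= 0 or r_nm <= 0:
        raise DomainError("R0 and r must be positive")
    ratio_ok = 0.5 * R0_nm < r_nm < 1.5 * R0_nm
    scale_ok = scale_nm[0] <= r_nm <= scale_nm[1]
    return FretValidity(ratio_ok=ratio_ok, scale_ok=scale_ok, ok=ratio_ok and scale_ok)


def efficiency_consistency(E: float, R0_nm: float, r_nm: float, tol: float = 0.05) -> tuple[float, bool]:
    """Compare an efficiency against the one implied by (R0, r).

    Returns the distance-route efficiency and whether the two agree within
    ``tol``; disagreement also raises a ConsistencyWarning.
    """
    E_dist = efficiency_from_distance(R0_nm, r_nm)
    agree = abs(E_dist - E) <= tol
    if not agree:
        warnings.warn(
            f"intensity-route E = {E:.3f} and distance-route E = {E_dist:.3f} "
            f"disagree by more than {tol}",
            ConsistencyWarning,
            stacklevel=2,
        )
    return E_dist, agree


@dataclass(frozen=True)
class FretResult:
    """Full FRET analysis product."""

    J_cm3_M1: float
    R0_nm: float
    E: float
    r_nm: float
    validity: FretValidity

    def __post_init__(self) -> None:
        if not (0 <= self.E <= 1):
            raise ValidationError("E must lie in [0, 1]")
        if self.J_cm3_M1 < 0 or self.R0_nm <= 0 or self.r_nm <= 0:
            raise ValidationError("J must be >= 0 and R0, r positive")


class FretAnalysis:
    """End-to-end FRET pipeline from spectra and a quenched intensity pair.

    J from the spectra, R0 from J and the photophysical constants, E from
    the intensity pair, and r by inverting the efficiency-distance relation.
    """

    def __init__(
        self,
        donor_emission: Spectrum,
        acceptor_extinction: Spectrum,
        F0: float,
        F: float,
        constants: Constants = DEFAULT_CONSTANTS,
    ) -> None:
        self.donor_emission = donor_emission
        self.acceptor_extinction = acceptor_extinction
        self.F0 = float(F0)
        self.F = float(F)
        self.constants = constants

    def run(self) -> FretResult:
        J = overlap_integral(self.donor_emission, self.acceptor_extinction)
        R0 = forster_radius(J, self.constants)
        E = efficiency_from_intensity(self.F, self.F0)
        r = distance_from_efficiency(E, R0)
        return FretResult(J_cm3_M1=J, R0_nm=R0, E=E, r_nm=r, validity=check_fret_validity(R0, r))
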