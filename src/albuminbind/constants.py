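"""Physical constants and photophysical defaults used across the analyses.

The defaults describe tryptophan fluorescence of serum albumin in aqueous
buffer: the unquenched excited-state lifetime tau0, the isotropic dynamic
orientation factor kappa^2 = 2/3, the refractive index of the buffer, and
the donor quantum yield. Energies are handled in cal/mol with
R = 1.987 cal K^-1 mol^-1; kcal appears only in reporting layers.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .exceptions import ValidationError

#: 0 degrees Celsius in Kelvin.
ZERO_CELSIUS_K = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    """Convert a Celsius temperature to Kelvin (K = degC + 273.15)."""
    return float(t_c) + ZERO_CELSIUS_K


@dataclass(frozen=True)
class Constants:
    """Registry of physical constants; all overridable, all validated.

    Attributes
    ----------
    tau0_s : float
        Unquenched donor excited-state lifetime in seconds.
    R_cal : float
        Gas constant in cal K^-1 mol^-1.
    kq_diffusion_limit_M1s1 : float
        Ceiling for diffusion-controlled bimolecular quenching; apparent
        rate constants above it indicate ground-state (static) complexes.
    kappa2 : float
        Dipole orientation factor; 2/3 for isotropic dynamic averaging.
    refractive_index : float
        Refractive index of the medium between donor and acceptor.
    quantum_yield : float
        Fluorescence quantum yield of the donor.
    """

    tau0_s: float = 5.78e-9
    R_cal: float = 1.987
    kq_diffusion_limit_M1s1: float = 2.0e10
    kappa2: float = 2.0 / 3.0
    refractive_index: float = 1.336
    quantum_yield: float = 0.118

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0):
                raise ValidationError(f"constant {f.name} must be strictly positive, got {v!r}")
        if not (0 < self.kappa2 <= 4):
            raise ValidationError(f"kappa2 must lie in (0, 4], got {self.kappa2!r}")


#: Module-level default registry.
DEFAULT_CONSTANTS = Constants()
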