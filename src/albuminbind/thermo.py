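"""van't Hoff analysis of temperature-dependent binding constants.

ln K is linear in 1/T when the binding enthalpy is constant over the
temperature range studied:

    ln K = -dH0/(R T) + dS0/R

so an ordinary least-squares line through (1/T, ln K) yields the binding
enthalpy dH0 (from the slope) and entropy dS0 (from the intercept); the
Gibbs energy follows as dG0 = dH0 - T dS0. Internal energies are cal/mol
with R = 1.987 cal K^-1 mol^-1; convert to kcal only for display.

The signs of dH0 and dS0 classify the dominant intermolecular forces:
a positive dS0 indicates hydrophobic interactions; a negative dH0
indicates hydrogen bonding and van der Waals contacts; a negative dG0
marks the binding as spontaneous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .constants import DEFAULT_CONSTANTS, Constants
from .exceptions import FitError, ValidationError
from .results import FitResultsMixin


class VantHoffModel:
    """Least-squares van't Hoff line through (1/T, ln K_b)."""

    def __init__(
        self,
        temperatures_K: Sequence[float],
        K_b: Sequence[float],
        constants: Constants = DEFAULT_CONSTANTS,
    ) -> None:
        T = np.asarray(temperatures_K, dtype=float)
        K = np.asarray(K_b, dtype=float)
        if T.ndim != 1 or K.shape != T.shape:
            raise ValidationError("temperatures_K and K_b must be aligned 1-D arrays")
        if T.size < 2:
            raise FitError("need binding constants at >= 2 temperatures")
        if np.unique(T).size != T.size:
            raise FitError("duplicate temperatures in van't Hoff input")
        if np.any(T <= 0):
            raise ValidationError("temperatures must be positive (Kelvin)")
        if np.any(K <= 0):
            raise ValidationError("binding constants must be strictly positive")
        order = np.argsort(T)
        self.temperatures_K = T[order]
        self.K_b = K[order]
        self.constants = constants

    def fit(self) -> "VantHoffResults":
        R = self.constants.R_cal
        x = 1.0 / self.temperatures_K
        y = np.log(self.K_b)
        reg = stats.linregress(x, y)
        dH = -R * float(reg.slope)
        dS = R * float(reg.intercept)
        dH_se = R * float(reg.stderr) if math.isfinite(reg.stderr) else float("nan")
        dS_se = R * float(reg.intercept_stderr) if math.isfinite(reg.intercept_stderr) else float("nan")
        return VantHoffResults(
            model=self,
            dH_cal_mol=dH,
            dH_cal_mol_se=dH_se,
            dS_cal_molK=dS,
            dS_cal_molK_se=dS_se,
            rsquared=float(reg.rvalue) ** 2,
            nobs=int(self.temperatures_K.size),
        )


@dataclass(frozen=True)
class VantHoffResults(FitResultsMixin):
    model: VantHoffModel
    dH_cal_mol: float
    dH_cal_mol_se: float
    dS_cal_molK: float
    dS_cal_molK_se: float
    rsquared: float
    nobs: int

    _param_names = ("dH_cal_mol", "dS_cal_molK")
    _extra_names = ("rsquared", "nobs")
    _title = "van't Hoff fit (ln K_b vs 1/T)"

    def gibbs(self, T_K: float) -> float:
        """dG0 at temperature T via dG0 = dH0 - T dS0 (cal/mol)."""
        return gibbs_energy(self.dH_cal_mol, self.dS_cal_molK, T_K)

    def binding_thermo(self, force_rules: bool = True) -> "BindingThermo":
        """Assemble the full per-temperature thermodynamic summary."""
        temps = self.model.temperatures_K
        dG = np.array([self.gibbs(t) for t in temps])
        label = ""
        if force_rules:
            cls = classify_forces(self.dH_cal_mol, self.dS_cal_molK, T_K=float(temps[0]))
            label = ", ".join(cls.labels) + (" (spontaneous)" if cls.spontaneous else "")
        return BindingThermo(
            temperatures_K=temps,
            K_b_by_T=self.model.K_b,
            dH_cal_mol=self.dH_cal_mol,
            dS_cal_molK=self.dS_cal_molK,
            dG_by_T_cal_mol=dG,
            force_label=label,
        )


@dataclass(frozen=True)
class BindingThermo:
    """Per-temperature K_b with fitted dH0, dS0, dG0(T) and force labels."""

    temperatures_K: np.ndarray
    K_b_by_T: np.ndarray
    dH_cal_mol: float
    dS_cal_molK: float
    dG_by_T_cal_mol: np.ndarray
    force_label: str = ""

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures_K, dtype=float)
        K = np.asarray(self.K_b_by_T, dtype=float)
        G = np.asarray(self.dG_by_T_cal_mol, dtype=float)
        object.__setattr__(self, "temperatures_K", T)
        object.__setattr__(self, "K_b_by_T", K)
        object.__setattr__(self, "dG_by_T_cal_mol", G)
        if not (T.shape == K.shape == G.shape) or T.size < 2:
            raise ValidationError("arrays must align with >= 2 temperatures")
        expected = self.dH_cal_mol - T * self.dS_cal_molK
        if not np.allclose(G, expected, rtol=1e-9, atol=1e-6):
            raise ValidationError("dG_by_T must equal dH - T*dS at every temperature")


def vant_hoff_fit(
    temperatures_K: Sequence[float],
    K_b: Sequence[float],
    constants: Constants = DEFAULT_CONSTANTS,
) -> VantHoffResults:
    """Convenience wrapper: fit ln K_b vs 1/T and return (dH0, dS0) results."""
    return VantHoffModel(temperatures_K, K_b, constants).fit()


def gibbs_energy(dH_cal_mol: float, dS_cal_molK: float, T_K: float) -> float:
    """dG0 = dH0 - T dS0 (all cal/mol, T in Kelvin)."""
    if T_K <= 0:
        raise ValidationError("T_K must be positive")
    return dH_cal_mol - T_K * dS_cal_molK


def gibbs_from_K(K_b: float, T_K: float, constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Cross-check route: dG0 = -R T ln K_b (cal/mol)."""
    if T_K <= 0:
        raise ValidationError("T_K must be positive")
    if K_b <= 0:
        raise ValidationError("K_b must be strictly positive")
    return -constants.R_cal * T_K * math.log(K_b)


@dataclass(frozen=True)
class ForceClassification:
    """Dominant interaction forces inferred from the signs of dH0 and dS0."""

    labels: tuple[str, ...]
    spontaneous: bool
    dG_cal_mol: float


def classify_forces(
    dH_cal_mol: float,
    dS_cal_molK: float,
    T_K: float = 298.15,
) -> ForceClassification:
    """Sign-convention force assignment.

    dS0 > 0 adds "hydrophobic"; dH0 < 0 adds "hydrogen bond / van der
    Waals"; dG0 = dH0 - T dS0 < 0 marks the binding spontaneous.
    """
    labels: list[str] = []
    if dS_cal_molK > 0:
        labels.append("hydrophobic")
    if dH_cal_mol < 0:
        labels.append("hydrogen bond / van der Waals")
    dG = gibbs_energy(dH_cal_mol, dS_cal_molK, T_K)
    return ForceClassification(tuple(labels), spontaneous=dG < 0, dG_cal_mol=dG)
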