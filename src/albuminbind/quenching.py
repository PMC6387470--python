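"""Fluorescence-quenching analysis of ligand binding to a protein.

The titration follows the tryptophan emission of the protein (emission
maximum near 340 nm) as ligand is added. Three layers:

* inner-filter correction ``F_corr = F_obs * exp((A_ex + A_em)/2)`` removes
  attenuation by the ligand's own absorbance at the excitation and emission
  wavelengths;
* the Stern-Volmer line ``F0/F = 1 + K_SV [Q]`` gives the quenching constant
  K_SV and, through the unquenched lifetime tau0, the apparent bimolecular
  quenching rate constant ``k_q = K_SV / tau0``;
* the double-logarithmic (modified Stern-Volmer) line
  ``log10(F0/F - 1) = log10 K_b + n log10 [Q]`` gives the binding constant
  K_b and stoichiometry n.

Whether quenching is static (ground-state complex) or dynamic (collisional)
is diagnosed from the temperature trend of K_SV together with the magnitude
of k_q relative to the diffusion-controlled ceiling (~2e10 M^-1 s^-1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DEFAULT_CONSTANTS, Constants, celsius_to_kelvin
from .exceptions import (
    DomainError,
    ExcludedPointWarning,
    FitError,
    InterceptWarning,
    ParameterError,
    ValidationError,
)
from .results import FitResultsMixin


@dataclass(frozen=True)
class QuenchTitration:
    """Fluorescence intensities versus quencher concentration at one temperature.

    The first row is the quencher-free reference (``quencher_M[0] == 0``).
    ``A_ex``/``A_em`` are optional per-point absorbances at the excitation
    and emission wavelengths for inner-filter correction.
    """

    temperature_K: float
    quencher_M: np.ndarray
    F_obs: np.ndarray
    A_ex: np.ndarray | None = None
    A_em: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.quencher_M, dtype=float)
        f = np.asarray(self.F_obs, dtype=float)
        object.__setattr__(self, "quencher_M", q)
        object.__setattr__(self, "F_obs", f)
        if self.temperature_K <= 0:
            raise ValidationError("temperature_K must be positive (absolute temperature)")
        if q.ndim != 1 or f.shape != q.shape:
            raise ValidationError("quencher_M and F_obs must be aligned 1-D arrays")
        if q.size < 4:
            raise ValidationError(f"a titration needs at least 4 points, got {q.size}")
        if q[0] != 0.0:
            raise ValidationError("first titration point must be quencher-free ([Q] = 0)")
        if np.any(q < 0) or not np.all(np.diff(q) > 0):
            raise ValidationError("quencher_M must be non-negative and strictly increasing")
        if np.any(f <= 0):
            raise ValidationError("fluorescence intensities must be strictly positive")
        for name in ("A_ex", "A_em"):
            a = getattr(self, name)
            if a is not None:
                a = np.asarray(a, dtype=float)
                object.__setattr__(self, name, a)
                if a.shape != q.shape:
                    raise ValidationError(f"{name} must align with quencher_M")
                if np.any(a < 0):
                    raise ValidationError(f"{name} absorbances must be >= 0")

    @classmethod
    def from_celsius(cls, temperature_C: float, quencher_M, F_obs, **kw) -> "QuenchTitration":
        return cls(celsius_to_kelvin(temperature_C), quencher_M, F_obs, **kw)

    @classmethod
    def from_csv(cls, path: str | Path, temperature_C: float, label: str | None = None) -> "QuenchTitration":
        """Read a wide titration table: first column [Q] in M, remaining
        columns replicate intensities (averaged)."""
        path = Path(path)
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        if df.shape[1] < 2:
            raise ValidationError(f"{path.name}: need a concentration column plus >= 1 intensity column")
        q = df.iloc[:, 0].to_numpy(dtype=float)
        f = df.iloc[:, 1:].to_numpy(dtype=float).mean(axis=1)
        return cls.from_celsius(temperature_C, q, f, label=label if label is not None else path.stem)

    @property
    def F0(self) -> float:
        """Unquenched reference intensity (the [Q] = 0 row)."""
        return float(self.F_obs[0])

    def corrected(self) -> np.ndarray:
        """Inner-filter-corrected intensities; requires A_ex and A_em."""
        if self.A_ex is None or self.A_em is None:
            raise ParameterError("titration carries no A_ex/A_em absorbances to correct with")
        return correct_inner_filter(self.F_obs, self.A_ex, self.A_em)


def correct_inner_filter(F_obs, A_ex, A_em):
    """Inner-filter correction: F_corr = F_obs * exp((A_ex + A_em) / 2)."""
    F_obs = np.asarray(F_obs, dtype=float)
    A_ex = np.asarray(A_ex, dtype=float)
    A_em = np.asarray(A_em, dtype=float)
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise ParameterError("absorbances must be >= 0")
    out = F_obs * np.exp((A_ex + A_em) / 2.0)
    return out if out.ndim else float(out)


class SternVolmerModel:
    """F0/F versus [Q] regression (intercept left free as a diagnostic).

    Parameters
    ----------
    titration : QuenchTitration
    constants : Constants
        Supplies tau0 for k_q = K_SV / tau0.
    apply_inner_filter : bool
        If True, correct intensities with the titration's absorbances first.
    """

    def __init__(
        self,
        titration: QuenchTitration,
        constants: Constants = DEFAULT_CONSTANTS,
        apply_inner_filter: bool = False,
    ) -> None:
        self.titration = titration
        self.constants = constants
        self.apply_inner_filter = apply_inner_filter

    def _intensities(self) -> np.ndarray:
        if self.apply_inner_filter:
            return self.titration.corrected()
        return self.titration.F_obs

    def fit(self) -> "SternVolmerResults":
        t = self.titration
        F = self._intensities()
        if np.any(F <= 0):
            raise DomainError("non-positive intensities after correction")
        if np.count_nonzero(t.quencher_M > 0) < 3:
            raise FitError("need at least 3 nonzero-quencher points for a Stern-Volmer fit")
        ratio = F[0] / F
        reg = stats.linregress(t.quencher_M, ratio)
        k_sv = float(reg.slope)
        intercept = float(reg.intercept)
        if math.isfinite(reg.intercept_stderr) and reg.intercept_stderr > 0:
            if abs(intercept - 1.0) > 3.0 * reg.intercept_stderr:
                warnings.warn(
                    f"Stern-Volmer intercept {intercept:.4g} deviates from 1 by more than "
                    f"3 SE ({reg.intercept_stderr:.2g}); residual inner-filter effects?",
                    InterceptWarning,
                    stacklevel=2,
                )
        return SternVolmerResults(
            model=self,
            K_SV=k_sv,
            K_SV_se=float(reg.stderr),
            intercept=intercept,
            intercept_se=float(reg.intercept_stderr),
            k_q=k_sv / self.constants.tau0_s,
            rsquared=float(reg.rvalue) ** 2,
            nobs=int(t.quencher_M.size),
        )


@dataclass(frozen=True)
class SternVolmerResults(FitResultsMixin):
    model: SternVolmerModel
    K_SV: float
    K_SV_se: float
    intercept: float
    intercept_se: float
    k_q: float
    rsquared: float
    nobs: int

    _param_names = ("K_SV", "intercept")
    _extra_names = ("k_q", "rsquared", "nobs")
    _title = "Stern-Volmer quenching fit (F0/F vs [Q])"


class DoubleLogBindingModel:
    """log10(F0/F - 1) versus log10[Q] regression for K_b and stoichiometry n.

    Points with F >= F0 at nonzero quencher (no net quenching; the log
    argument would be non-positive) are excluded with a warning.
    """

    def __init__(
        self,
        titration: QuenchTitration,
        apply_inner_filter: bool = False,
    ) -> None:
        self.titration = titration
        self.apply_inner_filter = apply_inner_filter

    def fit(self) -> "DoubleLogResults":
        t = self.titration
        F = t.corrected() if self.apply_inner_filter else t.F_obs
        F0 = F[0]
        nonzero = t.quencher_M > 0
        usable = nonzero & (F < F0)
        n_excluded = int(np.count_nonzero(nonzero) - np.count_nonzero(usable))
        if n_excluded:
            warnings.warn(
                f"{n_excluded} titration point(s) with F >= F0 excluded from the double-log fit",
                ExcludedPointWarning,
                stacklevel=2,
            )
        if np.count_nonzero(usable) < 3:
            raise FitError("fewer than 3 usable points for the double-log binding fit")
        x = np.log10(t.quencher_M[usable])
        y = np.log10(F0 / F[usable] - 1.0)
        reg = stats.linregress(x, y)
        K_b = 10.0 ** float(reg.intercept)
        K_b_se = math.log(10.0) * K_b * float(reg.intercept_stderr)
        return DoubleLogResults(
            model=self,
            K_b=K_b,
            K_b_se=K_b_se,
            n_stoich=float(reg.slope),
            n_stoich_se=float(reg.stderr),
            rsquared=float(reg.rvalue) ** 2,
            nobs=int(np.count_nonzero(usable)),
            n_excluded=n_excluded,
        )


@dataclass(frozen=True)
class DoubleLogResults(FitResultsMixin):
    model: DoubleLogBindingModel
    K_b: float
    K_b_se: float
    n_stoich: float
    n_stoich_se: float
    rsquared: float
    nobs: int
    n_excluded: int

    _param_names = ("K_b", "n_stoich")
    _extra_names = ("rsquared", "nobs", "n_excluded")
    _title = "Double-log binding fit (log10(F0/F - 1) vs log10[Q])"


def fit_stern_volmer(
    titration: QuenchTitration,
    constants: Constants = DEFAULT_CONSTANTS,
    apply_inner_filter: bool = False,
) -> SternVolmerResults:
    """Convenience wrapper: build and fit a SternVolmerModel."""
    return SternVolmerModel(titration, constants, apply_inner_filter).fit()


def fit_double_log(
    titration: QuenchTitration,
    apply_inner_filter: bool = False,
) -> DoubleLogResults:
    """Convenience wrapper: build and fit a DoubleLogBindingModel."""
    return DoubleLogBindingModel(titration, apply_inner_filter).fit()


@dataclass(frozen=True)
class QuenchFit:
    """Combined per-temperature quenching/binding summary (one table row)."""

    temperature_K: float
    K_SV: float
    K_SV_se: float
    k_q: float
    K_b: float
    K_b_se: float
    n_stoich: float
    n_stoich_se: float
    rsquared_sv: float
    rsquared_dl: float

    def __post_init__(self) -> None:
        if not (self.K_SV > 0 and self.K_b > 0 and self.n_stoich > 0):
            raise ValidationError("K_SV, K_b and n must be strictly positive")

    @classmethod
    def from_titration(
        cls,
        titration: QuenchTitration,
        constants: Constants = DEFAULT_CONSTANTS,
        apply_inner_filter: bool = False,
    ) -> "QuenchFit":
        sv = fit_stern_volmer(titration, constants, apply_inner_filter)
        dl = fit_double_log(titration, apply_inner_filter)
        return cls(
            temperature_K=titration.temperature_K,
            K_SV=sv.K_SV,
            K_SV_se=sv.K_SV_se,
            k_q=sv.k_q,
            K_b=dl.K_b,
            K_b_se=dl.K_b_se,
            n_stoich=dl.n_stoich,
            n_stoich_se=dl.n_stoich_se,
            rsquared_sv=sv.rsquared,
            rsquared_dl=dl.rsquared,
        )


@dataclass(frozen=True)
class QuenchingMechanism:
    """Outcome of the static/dynamic classification with failed criteria."""

    label: str  # "static" | "dynamic" | "indeterminate"
    reasons: tuple[str, ...] = ()


def classify_quenching(
    fits_by_T: Sequence[QuenchFit] | Sequence[SternVolmerResults],
    constants: Constants = DEFAULT_CONSTANTS,
    temperatures_K: Sequence[float] | None = None,
) -> QuenchingMechanism:
    """Diagnose the quenching mechanism from the temperature trend of K_SV.

    "static": K_SV strictly decreases with temperature AND every apparent
    k_q exceeds the diffusion-controlled limit (ground-state complex).
    "dynamic": K_SV strictly increases AND every k_q is at or below the
    limit (collisional). Anything else is "indeterminate", with the failed
    criteria listed.
    """
    fits = list(fits_by_T)
    if len(fits) < 2:
        raise ParameterError("need fits at >= 2 temperatures")
    if temperatures_K is None:
        temperatures_K = [getattr(f, "temperature_K", None) for f in fits]
        if any(t is None for t in temperatures_K):
            raise ParameterError("supply temperatures_K when fits carry no temperature")
    temps = np.asarray(temperatures_K, dtype=float)
    if not np.all(np.diff(temps) > 0):
        raise ParameterError("fits must be ordered by strictly increasing temperature")
    ksv = np.array([f.K_SV for f in fits])
    kq = np.array([f.k_q for f in fits])
    limit = constants.kq_diffusion_limit_M1s1
    decreasing = bool(np.all(np.diff(ksv) < 0))
    increasing = bool(np.all(np.diff(ksv) > 0))
    above = bool(np.all(kq > limit))
    below = bool(np.all(kq <= limit))
    if decreasing and above:
        return QuenchingMechanism("static")
    if increasing and below:
        return QuenchingMechanism("dynamic")
    reasons = []
    if not (decreasing or increasing):
        reasons.append("K_SV is not monotone in temperature")
    if decreasing and not above:
        reasons.append(f"K_SV decreases but some k_q <= diffusion limit {limit:g} M^-1 s^-1")
    if increasing and not below:
        reasons.append(f"K_SV increases but some k_q > diffusion limit {limit:g} M^-1 s^-1")
    return QuenchingMechanism("indeterminate", tuple(reasons))
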