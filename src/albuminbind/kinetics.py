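"""Esterase-kinetics analysis: Michaelis-Menten fits and inhibition mode.

Initial velocities of p-nitrophenyl acetate hydrolysis by serum albumin
are fitted to v = V_max S / (K_m + S), either by nonlinear least squares
(statistically preferred) or via the double-reciprocal Lineweaver-Burk
line 1/v = (K_m/V_max)(1/S) + 1/V_max. Catalytic constants follow from
the enzyme concentration: k_cat = V_max / [E], efficiency = k_cat / K_m.
Units are mM and minutes throughout.

Comparing fits across inhibitor doses classifies the inhibition mode:
an apparent K_m that rises while V_max is unchanged is the competitive
signature (inhibitor occupying the substrate site).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .exceptions import ExcludedPointWarning, FitError, ParameterError, ValidationError
from .results import FitResultsMixin


@dataclass(frozen=True)
class KineticsDataset:
    """Initial velocities versus substrate concentration at one inhibitor dose."""

    substrate_mM: np.ndarray
    v0_mM_min: np.ndarray
    enzyme_conc_mM: float
    inhibitor_ratio: str = "1:0"

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_mM, dtype=float)
        v = np.asarray(self.v0_mM_min, dtype=float)
        object.__setattr__(self, "substrate_mM", s)
        object.__setattr__(self, "v0_mM_min", v)
        if s.ndim != 1 or v.shape != s.shape:
            raise ValidationError("substrate_mM and v0_mM_min must be aligned 1-D arrays")
        if s.size < 5:
            raise ValidationError(f"a kinetics dataset needs at least 5 points, got {s.size}")
        if np.any(s < 0) or not np.all(np.diff(s) > 0):
            raise ValidationError("substrate_mM must be non-negative and strictly increasing")
        if np.any(v < 0):
            raise ValidationError("initial velocities must be >= 0")
        if self.enzyme_conc_mM <= 0:
            raise ValidationError("enzyme_conc_mM must be > 0")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        enzyme_conc_mM: float,
        inhibitor_ratio: str = "1:0",
    ) -> "KineticsDataset":
        path = Path(path)
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        s = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1:].to_numpy(dtype=float).mean(axis=1)
        order = np.argsort(s)
        return cls(s[order], v[order], enzyme_conc_mM, inhibitor_ratio)

    @property
    def dose(self) -> float:
        """Inhibitor dose parsed from the 'enzyme:inhibitor' ratio label."""
        m = re.fullmatch(r"\s*(\d+(?:\.\d+)?)\s*:\s*(\d+(?:\.\d+)?)\s*", self.inhibitor_ratio)
        if not m:
            raise ParameterError(f"cannot parse inhibitor ratio {self.inhibitor_ratio!r}")
        a, b = float(m.group(1)), float(m.group(2))
        if a == 0:
            raise ParameterError("enzyme part of the ratio must be nonzero")
        return b / a


def catalytic_constants(K_m: float, V_max: float, enzyme_conc: float) -> tuple[float, float]:
    """(k_cat, k_cat/K_m) from V_max and the enzyme concentration."""
    if enzyme_conc <= 0:
        raise ParameterError("enzyme_conc must be > 0")
    k_cat = V_max / enzyme_conc
    return k_cat, k_cat / K_m


class MichaelisMentenModel:
    """Michaelis-Menten fit of one dataset.

    ``method`` is "nonlinear" (default; least squares on the hyperbola) or
    "lineweaver_burk" (OLS on the double-reciprocal line; zero-substrate
    and zero-velocity points are excluded with a warning).
    """

    METHODS = ("nonlinear", "lineweaver_burk")

    def __init__(self, dataset: KineticsDataset, method: str = "nonlinear") -> None:
        if method not in self.METHODS:
            raise ParameterError(f"method must be one of {self.METHODS}")
        self.dataset = dataset
        self.method = method

    def fit(self) -> "MichaelisMentenResults":
        if self.method == "nonlinear":
            km, vmax, km_se, vmax_se, rsq, nobs = self._fit_nonlinear()
        else:
            km, vmax, km_se, vmax_se, rsq, nobs = self._fit_lineweaver_burk()
        if km <= 0 or vmax <= 0:
            raise FitError(f"negative/zero fitted parameters (K_m={km:.3g}, V_max={vmax:.3g})")
        k_cat, eff = catalytic_constants(km, vmax, self.dataset.enzyme_conc_mM)
        return MichaelisMentenResults(
            model=self,
            K_m_mM=km,
            K_m_mM_se=km_se,
            V_max_mM_min=vmax,
            V_max_mM_min_se=vmax_se,
            k_cat_min1=k_cat,
            efficiency_mM1_min1=eff,
            rsquared=rsq,
            nobs=nobs,
            method=self.method,
            inhibitor_ratio=self.dataset.inhibitor_ratio,
        )

    def _fit_nonlinear(self):
        s = self.dataset.substrate_mM
        v = self.dataset.v0_mM_min
        vmax0 = float(v.max()) or 1.0
        half = 0.5 * vmax0
        km0 = float(np.interp(half, v, s)) if np.any(v >= half) else float(np.median(s[s > 0]))
        km0 = max(km0, 1e-9)

        def f(S, vmax, km):
            return vmax * S / (km + S)

        try:
            popt, pcov = curve_fit(f, s, v, p0=[vmax0, km0], maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"Michaelis-Menten fit failed: {exc}") from exc
        perr = np.sqrt(np.diag(pcov))
        resid = v - f(s, *popt)
        sst = float(np.sum((v - v.mean()) ** 2))
        rsq = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
        return float(popt[1]), float(popt[0]), float(perr[1]), float(perr[0]), rsq, int(s.size)

    def _fit_lineweaver_burk(self):
        s = self.dataset.substrate_mM
        v = self.dataset.v0_mM_min
        usable = (s > 0) & (v > 0)
        excluded = int(np.count_nonzero(~usable))
        if excluded:
            warnings.warn(
                f"{excluded} zero-substrate/zero-velocity point(s) excluded from the "
                "Lineweaver-Burk fit",
                ExcludedPointWarning,
                stacklevel=3,
            )
        if np.count_nonzero(usable) < 3:
            raise FitError("fewer than 3 usable points for the Lineweaver-Burk fit")
        x = 1.0 / s[usable]
        y = 1.0 / v[usable]
        reg = stats.linregress(x, y)
        intercept, slope = float(reg.intercept), float(reg.slope)
        if intercept <= 0:
            raise FitError("non-positive Lineweaver-Burk intercept (V_max undefined)")
        vmax = 1.0 / intercept
        km = slope / intercept
        i_se = float(reg.intercept_stderr)
        s_se = float(reg.stderr)
        # first-order error propagation, neglecting slope/intercept covariance
        vmax_se = i_se / intercept**2
        km_se = math.hypot(s_se / intercept, slope * i_se / intercept**2)
        return km, vmax, km_se, vmax_se, float(reg.rvalue) ** 2, int(np.count_nonzero(usable))


@dataclass(frozen=True)
class MichaelisMentenResults(FitResultsMixin):
    model: MichaelisMentenModel
    K_m_mM: float
    K_m_mM_se: float
    V_max_mM_min: float
    V_max_mM_min_se: float
    k_cat_min1: float
    efficiency_mM1_min1: float
    rsquared: float
    nobs: int
    method: str
    inhibitor_ratio: str

    _param_names = ("K_m_mM", "V_max_mM_min")
    _extra_names = ("k_cat_min1", "efficiency_mM1_min1", "rsquared", "nobs", "method")
    _title = "Michaelis-Menten fit"


def fit_michaelis_menten(dataset: KineticsDataset, method: str = "nonlinear") -> MichaelisMentenResults:
    """Convenience wrapper: build and fit a MichaelisMentenModel."""
    return MichaelisMentenModel(dataset, method).fit()


@dataclass(frozen=True)
class InhibitionClassification:
    mode: str
    details: str = ""


def classify_inhibition(
    fits: Sequence[MichaelisMentenResults],
    doses: Sequence[float] | None = None,
    km_tol: float = 0.10,
    vmax_tol: float = 0.10,
) -> InhibitionClassification:
    """Classify the inhibition mode from apparent (K_m, V_max) across doses.

    Relative to the zero-dose fit: "competitive" when K_m rises
    monotonically beyond ``km_tol`` while every V_max stays within
    ``vmax_tol``; "noncompetitive" when V_max falls beyond tolerance with
    K_m unchanged; "uncompetitive" when both fall; "no inhibition" when
    both stay within tolerance; otherwise "mixed/indeterminate".
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ParameterError("need fits at >= 2 inhibitor doses including zero")
    if doses is None:
        doses = [f.model.dataset.dose for f in fits]
    doses = np.asarray(doses, dtype=float)
    if not np.all(np.diff(doses) > 0):
        raise ParameterError("fits must be ordered by strictly increasing inhibitor dose")
    if doses[0] != 0:
        raise ParameterError("the first fit must be the zero-inhibitor reference")
    km = np.array([f.K_m_mM for f in fits])
    vmax = np.array([f.V_max_mM_min for f in fits])
    km0, vmax0 = km[0], vmax[0]

    km_within = bool(np.all(np.abs(km - km0) <= km_tol * km0))
    vmax_within = bool(np.all(np.abs(vmax - vmax0) <= vmax_tol * vmax0))
    km_up = bool(np.all(np.diff(km) > 0) and km[-1] > (1 + km_tol) * km0)
    km_down = bool(np.all(np.diff(km) < 0) and km[-1] < (1 - km_tol) * km0)
    vmax_down = bool(np.all(np.diff(vmax) <= 0) and vmax[-1] < (1 - vmax_tol) * vmax0)

    detail = (
        f"K_m: {km0:.3g} -> {km[-1]:.3g} mM; V_max: {vmax0:.3g} -> {vmax[-1]:.3g} mM/min"
    )
    if km_within and vmax_within:
        return InhibitionClassification("no inhibition", detail)
    if km_up and vmax_within:
        return InhibitionClassification("competitive", detail)
    if km_within and vmax_down:
        return InhibitionClassification("noncompetitive", detail)
    if km_down and vmax_down:
        return InhibitionClassification("uncompetitive", detail)
    return InhibitionClassification("mixed/indeterminate", detail)
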