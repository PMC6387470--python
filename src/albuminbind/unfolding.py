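"""Two-state chemical-denaturation analysis (linear extrapolation method).

An optical probe y (here the 222 nm mean residue ellipticity) is followed
against denaturant molarity [g]. Under a two-state native <-> denatured
equilibrium with a linear free-energy dependence

    dG_D([g]) = dG_D0 - m_g [g]

the observed signal is the population-weighted mixture of the native and
denatured baselines:

    K([g]) = exp(-dG_D([g]) / (R T))
    y([g]) = (y_N([g]) + y_D([g]) K) / (1 + K)

Nonlinear least squares recovers dG_D0 (stability at zero denaturant,
cal/mol), the m-value m_g (cal mol^-1 M^-1) and the baselines; the
transition midpoint is C_m = dG_D0 / m_g. Baselines are flat by default
with an optional linear-in-[g] variant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import DEFAULT_CONSTANTS, Constants
from .exceptions import BaselineWarning, DomainError, FitError, RangeWarning, ValidationError
from .results import FitResultsMixin


@dataclass(frozen=True)
class UnfoldingCurve:
    """Optical signal versus denaturant molarity."""

    denaturant_M: np.ndarray
    y_obs: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.denaturant_M, dtype=float)
        y = np.asarray(self.y_obs, dtype=float)
        object.__setattr__(self, "denaturant_M", g)
        object.__setattr__(self, "y_obs", y)
        if g.ndim != 1 or y.shape != g.shape:
            raise ValidationError("denaturant_M and y_obs must be aligned 1-D arrays")
        if np.any(g < 0) or not np.all(np.diff(g) > 0):
            raise ValidationError("denaturant_M must be non-negative and strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "UnfoldingCurve":
        path = Path(path)
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        g = df.iloc[:, 0].to_numpy(dtype=float)
        y = df.iloc[:, 1:].to_numpy(dtype=float).mean(axis=1)
        order = np.argsort(g)
        return cls(g[order], y[order], label=label if label is not None else path.stem)


def fraction_denatured(y, yN: float, yD: float):
    """f_D = (y - y_N) / (y_D - y_N); values outside [-0.05, 1.05] flagged."""
    if yN == yD:
        raise DomainError("degenerate baselines: y_N == y_D")
    f = (np.asarray(y, dtype=float) - yN) / (yD - yN)
    if np.any(f < -0.05) or np.any(f > 1.05):
        warnings.warn(
            "fraction denatured outside [-0.05, 1.05]; baselines may be wrong",
            RangeWarning,
            stacklevel=2,
        )
    return f if f.ndim else float(f)


def _two_state_y(g, dG, m, yN, yD, sN=0.0, sD=0.0, RT=1.0):
    K = np.exp(-(dG - m * g) / RT)
    return ((yN + sN * g) + (yD + sD * g) * K) / (1.0 + K)


class TwoStateUnfoldingModel:
    """Nonlinear least-squares two-state transition fit.

    Parameters
    ----------
    curve : UnfoldingCurve
        Must have >= 8 points; a warning is raised when it does not span
        both baselines (>= 2 points with f_D < 0.2 and >= 2 with f_D > 0.8).
    T_K : float
        Absolute temperature of the experiment (default 298.15 K).
    baselines : {"flat", "linear"}
        Flat y_N, y_D or linear-in-[g] baselines.
    """

    def __init__(
        self,
        curve: UnfoldingCurve,
        T_K: float = 298.15,
        constants: Constants = DEFAULT_CONSTANTS,
        baselines: str = "flat",
    ) -> None:
        if len(curve.denaturant_M) < 8:
            raise ValidationError("a two-state fit needs at least 8 points")
        if baselines not in ("flat", "linear"):
            raise ValidationError("baselines must be 'flat' or 'linear'")
        if T_K <= 0:
            raise ValidationError("T_K must be positive")
        self.curve = curve
        self.T_K = float(T_K)
        self.constants = constants
        self.baselines = baselines
        self.RT = constants.R_cal * self.T_K

    # -- initialisation ----------------------------------------------------
    def _initial_guesses(self):
        g = self.curve.denaturant_M
        y = self.curve.y_obs
        n = g.size
        k = max(2, n // 10)
        yN0 = float(y[:k].mean())
        yD0 = float(y[-k:].mean())
        if yN0 == yD0:
            raise FitError("flat curve: cannot distinguish native and denatured baselines")
        fD = (y - yN0) / (yD0 - yN0)
        # midpoint from the f_D = 0.5 crossing
        idx = int(np.argmin(np.abs(fD - 0.5)))
        Cm0 = float(g[idx])
        if 0 < idx < n - 1 and fD[idx + 1] != fD[idx - 1]:
            # local linear interpolation of the crossing
            lo, hi = idx - 1, idx + 1
            Cm0 = float(np.interp(0.5, np.sort(fD[lo:hi + 1]), g[lo:hi + 1][np.argsort(fD[lo:hi + 1])]))
        Cm0 = min(max(Cm0, g[1] if n > 1 else 0.1), g[-1])
        # m from a logit-line slope through the transition region
        core = (fD > 0.05) & (fD < 0.95)
        m0 = None
        if np.count_nonzero(core) >= 2:
            logit = np.log(fD[core] / (1.0 - fD[core]))
            slope = np.polyfit(g[core], logit, 1)[0]
            if slope > 0:
                m0 = slope * self.RT
        if m0 is None or not math.isfinite(m0):
            span = max(g[-1] - g[0], 1e-6)
            m0 = 6.0 * self.RT / span  # generic sigmoid-width heuristic
        return yN0, yD0, Cm0, m0

    # -- fitting -----------------------------------------------------------
    def fit(self) -> "TwoStateResults":
        g = self.curve.denaturant_M
        y = self.curve.y_obs
        yN0, yD0, Cm0, m0 = self._initial_guesses()
        linear = self.baselines == "linear"
        RT = self.RT

        if linear:
            def f(gv, dG, m, yN, yD, sN, sD):
                return _two_state_y(gv, dG, m, yN, yD, sN, sD, RT=RT)
            lower = [0.0, 0.0, -np.inf, -np.inf, -np.inf, -np.inf]
            upper = [np.inf] * 6
        else:
            def f(gv, dG, m, yN, yD):
                return _two_state_y(gv, dG, m, yN, yD, RT=RT)
            lower = [0.0, 0.0, -np.inf, -np.inf]
            upper = [np.inf] * 4

        best = None
        diagnostics = []
        for scale in (1.0, 0.5, 2.0):
            m_try = m0 * scale
            p0 = [max(m_try * Cm0, RT), m_try, yN0, yD0]
            if linear:
                p0 += [0.0, 0.0]
            try:
                popt, pcov = curve_fit(
                    f, g, y, p0=p0, bounds=(lower, upper), maxfev=20000
                )
            except (RuntimeError, ValueError) as exc:
                diagnostics.append(f"start m={m_try:.3g}: {exc}")
                continue
            ssr = float(np.sum((f(g, *popt) - y) ** 2))
            if best is None or ssr < best[2]:
                best = (popt, pcov, ssr)
        if best is None:
            raise FitError("two-state fit did not converge from any start; " + "; ".join(diagnostics))
        popt, pcov, ssr = best
        perr = np.sqrt(np.diag(pcov))
        dG, m = float(popt[0]), float(popt[1])
        if m <= 0 or dG <= 0:
            raise FitError(f"unphysical two-state parameters (dG={dG:.3g}, m={m:.3g})")
        Cm = dG / m
        # delta-method SE for Cm = dG/m using the (dG, m) covariance block
        jac = np.array([1.0 / m, -dG / m**2])
        Cm_se = float(np.sqrt(jac @ pcov[:2, :2] @ jac))
        sst = float(np.sum((y - y.mean()) ** 2))
        # baseline coverage, judged from the fitted transition
        K_fit = np.exp(-(dG - m * g) / RT)
        fD_fit = K_fit / (1.0 + K_fit)
        n_native = int(np.count_nonzero(fD_fit < 0.2))
        n_denat = int(np.count_nonzero(fD_fit > 0.8))
        if n_native < 2 or n_denat < 2:
            warnings.warn(
                "curve does not clearly span both baselines "
                f"({n_native} native-like, {n_denat} denatured-like points)",
                BaselineWarning,
                stacklevel=2,
            )
        return TwoStateResults(
            model=self,
            dG_cal_mol=dG,
            dG_cal_mol_se=float(perr[0]),
            m_cal_mol_M=m,
            m_cal_mol_M_se=float(perr[1]),
            C_m_M=Cm,
            C_m_M_se=Cm_se,
            yN=float(popt[2]),
            yN_se=float(perr[2]),
            yD=float(popt[3]),
            yD_se=float(perr[3]),
            yN_slope=float(popt[4]) if linear else 0.0,
            yD_slope=float(popt[5]) if linear else 0.0,
            rsquared=1.0 - ssr / sst if sst > 0 else float("nan"),
            nobs=int(g.size),
        )


@dataclass(frozen=True)
class TwoStateResults(FitResultsMixin):
    model: TwoStateUnfoldingModel
    dG_cal_mol: float
    dG_cal_mol_se: float
    m_cal_mol_M: float
    m_cal_mol_M_se: float
    C_m_M: float
    C_m_M_se: float
    yN: float
    yN_se: float
    yD: float
    yD_se: float
    yN_slope: float
    yD_slope: float
    rsquared: float
    nobs: int

    _param_names = ("dG_cal_mol", "m_cal_mol_M", "C_m_M", "yN", "yD")
    _extra_names = ("rsquared", "nobs")
    _title = "Two-state denaturation fit (linear extrapolation)"

    def predict(self, denaturant_M) -> np.ndarray:
        g = np.asarray(denaturant_M, dtype=float)
        return _two_state_y(
            g, self.dG_cal_mol, self.m_cal_mol_M, self.yN, self.yD,
            self.yN_slope, self.yD_slope, RT=self.model.RT,
        )

    def fraction_denatured(self, denaturant_M) -> np.ndarray:
        """Model f_D([g]) = K/(1+K); exactly 0.5 at C_m."""
        g = np.asarray(denaturant_M, dtype=float)
        K = np.exp(-(self.dG_cal_mol - self.m_cal_mol_M * g) / self.model.RT)
        out = K / (1.0 + K)
        return out if out.ndim else float(out)


def fit_two_state(
    curve: UnfoldingCurve,
    T_K: float = 298.15,
    constants: Constants = DEFAULT_CONSTANTS,
    baselines: str = "flat",
) -> TwoStateResults:
    """Convenience wrapper: build and fit a TwoStateUnfoldingModel."""
    return TwoStateUnfoldingModel(curve, T_K, constants, baselines).fit()


@dataclass(frozen=True)
class StabilityShift:
    """Ligand-induced change in unfolding stability between two fits."""

    ddG_cal_mol: float
    dC_m_M: float
    stabilized: bool


def stability_shift(ref: TwoStateResults, test: TwoStateResults) -> StabilityShift:
    """ddG = dG_test - dG_ref and dC_m = C_m,test - C_m,ref.

    ``stabilized`` is True when both shifts are positive.
    """
    ddG = test.dG_cal_mol - ref.dG_cal_mol
    dCm = test.C_m_M - ref.C_m_M
    return StabilityShift(ddG_cal_mol=ddG, dC_m_M=dCm, stabilized=ddG > 0 and dCm > 0)
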