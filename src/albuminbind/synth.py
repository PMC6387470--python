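"""Seeded synthetic-data generators for every stage of the pipeline.

Each generator draws from the forward model the corresponding analysis
stage fits, with known ground-truth parameters, so generate -> fit
round-trips are the package's principal self-test. Defaults mirror the
study conditions this package was built around: a single-tryptophan
albumin donor (emission maximum 340 nm), binding constants near
1.6e4 M^-1 over a 0-100 uM ligand titration, a GdmCl unfolding midpoint
near 2.5 M, and p-NPA esterase kinetics with K_m ~ 0.35 mM over
0.05-0.8 mM substrate.

Noise models: "none", "gaussian_additive" (sigma = noise_level * signal
scale) and "lognormal_multiplicative" (factor exp(N(0, noise_level))).
Identical SynthConfig values give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import celsius_to_kelvin
from .exceptions import ParameterError, ValidationError
from .kinetics import KineticsDataset
from .quenching import QuenchTitration
from .spectra import Spectrum
from .unfolding import UnfoldingCurve

NOISE_MODELS = ("none", "gaussian_additive", "lognormal_multiplicative")


@dataclass(frozen=True)
class SynthConfig:
    """Reproducibility contract for one synthetic draw."""

    seed: int = 0
    noise_model: str = "none"
    noise_level: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_model not in NOISE_MODELS:
            raise ValidationError(f"noise_model must be one of {NOISE_MODELS}")
        if self.noise_level < 0:
            raise ValidationError("noise_level must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: Stage defaults per the package's noise policy: 1% lognormal for
#: fluorescence, 2% additive Gaussian for CD signals and velocities.
FLUOR_NOISE = SynthConfig(seed=0, noise_model="lognormal_multiplicative", noise_level=0.01)
SIGNAL_NOISE = SynthConfig(seed=0, noise_model="gaussian_additive", noise_level=0.02)


def _apply_noise(
    values: np.ndarray,
    cfg: SynthConfig,
    rng: np.random.Generator,
    scale: float,
    n_replicates: int = 1,
) -> np.ndarray:
    """Noisy measurement of ``values``, averaged over independent replicates."""
    if cfg.noise_model == "none" or cfg.noise_level == 0:
        return values.copy()
    shape = (n_replicates,) + values.shape
    if cfg.noise_model == "gaussian_additive":
        reps = values + rng.normal(0.0, cfg.noise_level * scale, size=shape)
    else:
        reps = values * np.exp(rng.normal(0.0, cfg.noise_level, size=shape))
    return reps.mean(axis=0)


DEFAULT_QUENCHER_GRID_M = np.linspace(0.0, 2.5e-4, 11)


def gen_quench_titration(
    K_b: float = 1.6e4,
    n_stoich: float = 1.0,
    F0: float = 2546.0,
    quencher_M: Sequence[float] = DEFAULT_QUENCHER_GRID_M,
    temperature_C: float = 25.0,
    cfg: SynthConfig = SynthConfig(),
    n_replicates: int = 3,
    include_absorbance: bool = False,
    ex_absorptivity_M1cm1: float = 1500.0,
    em_absorptivity_M1cm1: float = 500.0,
) -> QuenchTitration:
    """Quenching titration from F = F0 / (1 + K_b [Q]^n).

    For ``n_stoich = 1`` this is exactly the Stern-Volmer ground-state
    complex model with K_SV = K_b. The default grid spans the binding
    transition (F0/F from 1 to ~5 at the default K_b), and each reported
    intensity is the mean of ``n_replicates`` independent noisy trials;
    the [Q] = 0 row is the exact reference F0 by construction. With
    ``include_absorbance`` the ligand's own absorbances at the
    excitation/emission wavelengths attenuate the observed signal
    (inner-filter effect), and A_ex/A_em columns are attached so the
    correction can be exercised.
    """
    if K_b <= 0 or F0 <= 0 or n_stoich <= 0:
        raise ParameterError("K_b, F0 and n_stoich must be positive")
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    q = np.asarray(quencher_M, dtype=float)
    if q.ndim != 1 or q.size < 4 or q[0] != 0 or not np.all(np.diff(q) > 0):
        raise ParameterError("quencher grid must start at 0 and increase, length >= 4")
    rng = cfg.rng()
    F_true = F0 / (1.0 + K_b * q**n_stoich)
    A_ex = A_em = None
    if include_absorbance:
        A_ex = ex_absorptivity_M1cm1 * q
        A_em = em_absorptivity_M1cm1 * q
        F_true = F_true * np.exp(-(A_ex + A_em) / 2.0)
    F_obs = _apply_noise(F_true, cfg, rng, scale=F0, n_replicates=n_replicates)
    F_obs[0] = F_true[0]  # quencher-free reference row is exact
    return QuenchTitration(
        temperature_K=celsius_to_kelvin(temperature_C),
        quencher_M=q,
        F_obs=F_obs,
        A_ex=A_ex,
        A_em=A_em,
        label=f"synthetic quench (seed={cfg.seed})",
    )


def gen_band_spectra(
    donor_center_nm: float = 340.0,
    donor_sd_nm: float = 15.0,
    acceptor_center_nm: float = 335.0,
    acceptor_sd_nm: float = 25.0,
    acceptor_eps_max: float = 4000.0,
    grid_nm: Sequence[float] | None = None,
    cfg: SynthConfig = SynthConfig(),
) -> tuple[Spectrum, Spectrum]:
    """Gaussian donor-emission and acceptor-extinction bands.

    Donor peaks at 1 a.u.; acceptor in M^-1 cm^-1. Defaults emulate the
    overlap of a tryptophan emission band (max 340 nm) with a ligand
    absorption tail, giving an overlap integral of order 1e-15 cm^3 M^-1.
    """
    if donor_sd_nm <= 0 or acceptor_sd_nm <= 0:
        raise ParameterError("band widths must be positive")
    if grid_nm is None:
        grid_nm = np.arange(280.0, 420.0 + 1e-9, 1.0)
    grid = np.asarray(grid_nm, dtype=float)
    rng = cfg.rng()
    donor_sig = np.exp(-0.5 * ((grid - donor_center_nm) / donor_sd_nm) ** 2)
    acc_sig = acceptor_eps_max * np.exp(-0.5 * ((grid - acceptor_center_nm) / acceptor_sd_nm) ** 2)
    donor_sig = np.clip(_apply_noise(donor_sig, cfg, rng, scale=1.0), 0.0, None)
    acc_sig = np.clip(_apply_noise(acc_sig, cfg, rng, scale=acceptor_eps_max), 0.0, None)
    donor = Spectrum(grid, donor_sig, signal_kind="fluorescence_au", label="synthetic donor emission")
    acceptor = Spectrum(grid, acc_sig, signal_kind="molar_extinction_M1cm1", label="synthetic acceptor extinction")
    return donor, acceptor


DEFAULT_DENATURANT_GRID_M = np.linspace(0.0, 6.0, 25)


def gen_unfolding_curve(
    dG_cal: float = 4920.0,
    m_cal_M: float = 1980.0,
    yN: float = -18700.0,
    yD: float = -3000.0,
    grid_M: Sequence[float] = DEFAULT_DENATURANT_GRID_M,
    T_K: float = 298.15,
    R_cal: float = 1.987,
    cfg: SynthConfig = SynthConfig(),
) -> UnfoldingCurve:
    """Two-state denaturation curve y(g) with flat baselines.

    Defaults are the albumin stability parameters (dG_D0 = 4.92 kcal/mol,
    m = 1.98 kcal mol^-1 M^-1, midpoint 2.48 M) with MRE-like baselines.
    Gaussian additive noise is scaled by the baseline separation |yD - yN|.
    """
    if dG_cal <= 0 or m_cal_M <= 0:
        raise ParameterError("dG_cal and m_cal_M must be positive")
    g = np.asarray(grid_M, dtype=float)
    rng = cfg.rng()
    K = np.exp(-(dG_cal - m_cal_M * g) / (R_cal * T_K))
    y = (yN + yD * K) / (1.0 + K)
    y = _apply_noise(y, cfg, rng, scale=abs(yD - yN))
    return UnfoldingCurve(g, y, label=f"synthetic unfolding (seed={cfg.seed})")


DEFAULT_SUBSTRATE_GRID_MM = np.linspace(0.05, 0.8, 8)


def gen_kinetics(
    K_m_mM: float = 0.348,
    V_max: float = 10.2e-4,
    K_i_mM: float = 0.088,
    inhibitor_mM_list: Sequence[float] = (0.0, 0.04, 0.08),
    substrate_grid_mM: Sequence[float] = DEFAULT_SUBSTRATE_GRID_MM,
    enzyme_conc_mM: float = 8.0e-3,
    cfg: SynthConfig = SynthConfig(),
) -> list[KineticsDataset]:
    """Competitive-inhibition kinetics series, one dataset per dose.

    v = V_max S / (K_m (1 + [I]/K_i) + S) + noise. Ratio labels are
    derived from [I] relative to the enzyme concentration (e.g. "1:5").
    """
    if K_m_mM <= 0 or V_max <= 0 or K_i_mM <= 0:
        raise ParameterError("K_m, V_max and K_i must be positive")
    s = np.asarray(substrate_grid_mM, dtype=float)
    rng = cfg.rng()
    out: list[KineticsDataset] = []
    for inh in inhibitor_mM_list:
        if inh < 0:
            raise ParameterError("inhibitor concentrations must be >= 0")
        km_app = K_m_mM * (1.0 + inh / K_i_mM)
        v = V_max * s / (km_app + s)
        v = np.clip(_apply_noise(v, cfg, rng, scale=V_max), 0.0, None)
        ratio = f"1:{inh / enzyme_conc_mM:g}"
        out.append(KineticsDataset(s, v, enzyme_conc_mM, inhibitor_ratio=ratio))
    return out


# -- CSV writers matching the readers' dialects ---------------------------

def write_titration_csv(t: QuenchTitration, path: str | Path) -> None:
    """Write a titration in the wide format QuenchTitration.from_csv reads."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write("# quencher_M,F_obs\n")
        fh.write("quencher_M,F_obs\n")
        for q, f in zip(t.quencher_M, t.F_obs):
            fh.write(f"{float(q)!r},{float(f)!r}\n")


def write_unfolding_csv(c: UnfoldingCurve, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write("# denaturant_M,y_obs\n")
        fh.write("denaturant_M,y_obs\n")
        for g, y in zip(c.denaturant_M, c.y_obs):
            fh.write(f"{float(g)!r},{float(y)!r}\n")


def write_kinetics_csv(d: KineticsDataset, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write(f"# inhibitor ratio {d.inhibitor_ratio}; enzyme {d.enzyme_conc_mM!r} mM\n")
        fh.write("substrate_mM,v0_mM_min\n")
        for s, v in zip(d.substrate_mM, d.v0_mM_min):
            fh.write(f"{float(s)!r},{float(v)!r}\n")
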