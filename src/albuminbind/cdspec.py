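"""Circular-dichroism post-processing: mean residue ellipticity and helicity.

The observed far-UV ellipticity (millidegrees) is normalised to a
per-residue molar quantity,

    MRE = theta_obs / (10 * n_bonds * C * l)    [deg cm^2 dmol^-1]

with C the protein molar concentration, l the path length in cm and
n_bonds = n_residues - 1 peptide bonds (584 for the 585-residue serum
albumin chain). The alpha-helix fraction follows from the single-wavelength
estimator at 222 nm (Chen-style):

    %helix = (|MRE_222| - 2340) / 30300 * 100

Helical MRE at 222 nm is negative; the estimator is applied to the
magnitude by default (a sign-strict mode that requires a negative MRE is
available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, RangeWarning, ValidationError

HELIX_MRE_OFFSET = 2340.0
HELIX_MRE_SLOPE = 30300.0


@dataclass(frozen=True)
class CdSample:
    """A single-wavelength CD observation with its normalisation factors."""

    theta_obs_mdeg: float
    protein_conc_M: float
    n_residues: int = 585
    path_length_cm: float = 0.1
    wavelength_nm: float = 222.0

    def __post_init__(self) -> None:
        if self.protein_conc_M <= 0:
            raise DomainError("protein_conc_M must be > 0")
        if self.path_length_cm <= 0:
            raise ValidationError("path_length_cm must be > 0")
        if self.n_residues < 2:
            raise ValidationError("n_residues must be >= 2")

    @property
    def n_bonds(self) -> int:
        return self.n_residues - 1


def mean_residue_ellipticity(sample: CdSample) -> float:
    """MRE in deg cm^2 dmol^-1 from an observed ellipticity in mdeg."""
    return sample.theta_obs_mdeg / (
        10.0 * sample.n_bonds * sample.protein_conc_M * sample.path_length_cm
    )


def helix_percent(mre222: float, convention: str = "magnitude") -> float:
    """Alpha-helix percentage from the 222 nm mean residue ellipticity.

    ``convention="magnitude"`` (default) applies the estimator to |MRE|;
    ``"strict"`` requires MRE <= 0 and uses -MRE. Results are clamped to
    [0, 100] with a warning when the raw value falls outside.
    """
    if not np.isfinite(mre222):
        raise DomainError("MRE222 must be finite")
    if convention == "magnitude":
        magnitude = abs(mre222)
    elif convention == "strict":
        if mre222 > 0:
            raise DomainError("strict convention requires a non-positive (helical) MRE at 222 nm")
        magnitude = -mre222
    else:
        raise ValidationError(f"unknown convention {convention!r}")
    pct = (magnitude - HELIX_MRE_OFFSET) / HELIX_MRE_SLOPE * 100.0
    if pct < 0 or pct > 100:
        warnings.warn(
            f"helix estimate {pct:.1f}% outside [0, 100]; clamped", RangeWarning, stacklevel=2
        )
        pct = min(max(pct, 0.0), 100.0)
    return pct


def mre_for_helix_percent(pct: float) -> float:
    """Inverse of the helix estimator: |MRE_222| giving ``pct`` % helix."""
    if not (0 <= pct <= 100):
        raise DomainError("pct must lie in [0, 100]")
    return HELIX_MRE_OFFSET + HELIX_MRE_SLOPE * pct / 100.0


def helix_change_table(mre_by_condition, convention: str = "magnitude") -> pd.DataFrame:
    """Per-condition helix content and change versus the first condition.

    ``mre_by_condition`` is an ordered mapping or sequence of
    (label, MRE222) pairs; the first entry is the reference (free protein).
    """
    if hasattr(mre_by_condition, "items"):
        items = list(mre_by_condition.items())
    else:
        items = [(str(lbl), float(v)) for lbl, v in mre_by_condition]
    if not items:
        raise ValidationError("need at least one condition")
    rows = []
    ref_pct = None
    for label, mre in items:
        pct = helix_percent(mre, convention=convention)
        if ref_pct is None:
            ref_pct = pct
        rows.append({
            "condition": label,
            "MRE222_deg_cm2_dmol": float(mre),
            "helix_pct": pct,
            "delta_helix_pct": pct - ref_pct,
        })
    return pd.DataFrame(rows)
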