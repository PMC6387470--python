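"""Run-configuration handling and report assembly for the command line.

A run config is a nested mapping (YAML on disk) selecting stages and
their inputs; unknown keys are rejected so typos fail loudly. Each stage
writes a CSV table shaped like the study's summary tables plus a JSON
record with full precision, and a run log collecting the constants used
and every warning raised.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import cdspec, fret, kinetics, quenching, thermo, unfolding
from .constants import DEFAULT_CONSTANTS, Constants, celsius_to_kelvin
from .exceptions import AlbuminBindError, ValidationError
from .results import format_sig
from .spectra import read_spectrum

_KNOWN_TOP = {"outdir", "seed", "constants", "quench", "fret", "cd", "unfold", "kinetics"}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: Path = Path("albuminbind-out")
    seed: int = 0
    constants: Constants = DEFAULT_CONSTANTS
    quench: dict | None = None
    fret: dict | None = None
    cd: dict | None = None
    unfold: dict | None = None
    kinetics: dict | None = None

    @classmethod
    def from_mapping(cls, cfg: Mapping[str, Any]) -> "RunConfig":
        unknown = set(cfg) - _KNOWN_TOP
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        overrides = dict(cfg.get("constants") or {})
        constants = Constants(**overrides)  # raises on unknown/invalid overrides
        return cls(
            outdir=Path(cfg.get("outdir", "albuminbind-out")),
            seed=int(cfg.get("seed", 0)),
            constants=constants,
            quench=cfg.get("quench"),
            fret=cfg.get("fret"),
            cd=cfg.get("cd"),
            unfold=cfg.get("unfold"),
            kinetics=cfg.get("kinetics"),
        )

    @property
    def stages(self) -> list[str]:
        return [s for s in ("quench", "fret", "cd", "unfold", "kinetics") if getattr(self, s)]


def _round_table(df: pd.DataFrame, sig: int = 3) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda x: float(format_sig(x, sig)) if math.isfinite(x) else x)
    return out


def _stage_quench(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    spec = cfg.quench or {}
    inner = bool(spec.get("inner_filter", False))
    fits = []
    for entry in spec.get("titrations", []):
        t = quenching.QuenchTitration.from_csv(entry["file"], temperature_C=float(entry["temperature_c"]))
        fits.append(quenching.QuenchFit.from_titration(t, cfg.constants, apply_inner_filter=inner))
    if len(fits) < 1:
        raise ValidationError("quench stage needs at least one titration entry")
    fits.sort(key=lambda f: f.temperature_K)
    rows = [asdict(f) for f in fits]
    table = pd.DataFrame(rows)
    record: dict[str, Any] = {"fits": rows}
    if len(fits) >= 2:
        mech = quenching.classify_quenching(fits, cfg.constants)
        record["mechanism"] = {"label": mech.label, "reasons": list(mech.reasons)}
        vh = thermo.vant_hoff_fit([f.temperature_K for f in fits], [f.K_b for f in fits], cfg.constants)
        bt = vh.binding_thermo()
        record["vant_hoff"] = {
            "dH_cal_mol": vh.dH_cal_mol,
            "dH_cal_mol_se": vh.dH_cal_mol_se,
            "dS_cal_molK": vh.dS_cal_molK,
            "dS_cal_molK_se": vh.dS_cal_molK_se,
            "dG_by_T_cal_mol": bt.dG_by_T_cal_mol.tolist(),
            "force_label": bt.force_label,
        }
        table["dG_cal_mol"] = bt.dG_by_T_cal_mol
    return table, record


def _stage_fret(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    spec = cfg.fret or {}
    donor = read_spectrum(spec["donor"], kind="fluorescence_au")
    acceptor = read_spectrum(spec["acceptor"], kind="molar_extinction_M1cm1")
    res = fret.FretAnalysis(donor, acceptor, F0=float(spec["f0"]), F=float(spec["f"]), constants=cfg.constants).run()
    record = {
        "J_cm3_M1": res.J_cm3_M1,
        "R0_nm": res.R0_nm,
        "E": res.E,
        "r_nm": res.r_nm,
        "validity": asdict(res.validity),
    }
    table = pd.DataFrame([{k: v for k, v in record.items() if k != "validity"} | asdict(res.validity)])
    return table, record


def _stage_cd(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    spec = cfg.cd or {}
    conc = float(spec["conc_m"])
    residues = int(spec.get("residues", 585))
    path_cm = float(spec.get("path_cm", 0.1))
    mre_pairs = []
    for entry in spec.get("conditions", []):
        sample = cdspec.CdSample(
            theta_obs_mdeg=float(entry["theta_mdeg"]),
            protein_conc_M=conc,
            n_residues=residues,
            path_length_cm=path_cm,
        )
        mre_pairs.append((entry.get("label", f"condition {len(mre_pairs)}"),
                          cdspec.mean_residue_ellipticity(sample)))
    table = cdspec.helix_change_table(mre_pairs)
    return table, {"conditions": table.to_dict(orient="records")}


def _stage_unfold(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    spec = cfg.unfold or {}
    T_K = celsius_to_kelvin(float(spec.get("temp_c", 25.0)))
    baselines = spec.get("baselines", "flat")
    results = []
    for entry in spec.get("curves", []):
        curve = unfolding.UnfoldingCurve.from_csv(entry["file"], label=entry.get("label"))
        results.append(unfolding.fit_two_state(curve, T_K=T_K, constants=cfg.constants, baselines=baselines))
    if not results:
        raise ValidationError("unfold stage needs at least one curve entry")
    rows = []
    for res in results:
        rows.append({
            "label": res.model.curve.label,
            "dG_kcal_mol": res.dG_cal_mol / 1000.0,
            "dG_kcal_mol_se": res.dG_cal_mol_se / 1000.0,
            "m_kcal_mol_M": res.m_cal_mol_M / 1000.0,
            "C_m_M": res.C_m_M,
            "rsquared": res.rsquared,
        })
    record: dict[str, Any] = {"fits": rows}
    if len(results) >= 2:
        shift = unfolding.stability_shift(results[0], results[1])
        record["stability_shift"] = asdict(shift)
    return pd.DataFrame(rows), record


def _stage_kinetics(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    spec = cfg.kinetics or {}
    enzyme = float(spec["enzyme_mm"])
    method = {"lb": "lineweaver_burk", "nls": "nonlinear"}.get(spec.get("method", "nonlinear"),
                                                               spec.get("method", "nonlinear"))
    fits = []
    for entry in spec.get("datasets", []):
        d = kinetics.KineticsDataset.from_csv(entry["file"], enzyme_conc_mM=enzyme,
                                              inhibitor_ratio=entry.get("ratio", "1:0"))
        fits.append(kinetics.fit_michaelis_menten(d, method=method))
    if not fits:
        raise ValidationError("kinetics stage needs at least one dataset entry")
    rows = [{
        "ratio": f.inhibitor_ratio,
        "V_max_mM_min": f.V_max_mM_min,
        "K_m_mM": f.K_m_mM,
        "k_cat_min1": f.k_cat_min1,
        "efficiency_mM1_min1": f.efficiency_mM1_min1,
        "rsquared": f.rsquared,
    } for f in fits]
    record: dict[str, Any] = {"fits": rows, "method": method}
    if len(fits) >= 2:
        mode = kinetics.classify_inhibition(fits)
        record["inhibition"] = {"mode": mode.mode, "details": mode.details}
    return pd.DataFrame(rows), record


_STAGE_RUNNERS = {
    "quench": _stage_quench,
    "fret": _stage_fret,
    "cd": _stage_cd,
    "unfold": _stage_unfold,
    "kinetics": _stage_kinetics,
}


@dataclass
class ReportBundle:
    """Output of a pipeline run: per-stage tables, records and the log."""

    outdir: Path
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    records: dict[str, dict] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def run_pipeline(config: RunConfig | Mapping[str, Any]) -> ReportBundle:
    """Execute the configured stages and write CSV + JSON + log to outdir.

    Missing input files are listed collectively before aborting. Stage
    failures propagate as AlbuminBindError naming the stage.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_mapping(config)
    missing = []
    for stage in config.stages:
        spec = getattr(config, stage) or {}
        for key in ("file", "donor", "acceptor"):
            if key in spec and not Path(spec[key]).exists():
                missing.append(str(spec[key]))
        for entry in spec.get("titrations", []) + spec.get("curves", []) + spec.get("datasets", []):
            if not Path(entry["file"]).exists():
                missing.append(str(entry["file"]))
    if missing:
        raise ValidationError("missing input files: " + ", ".join(sorted(set(missing))))

    bundle = ReportBundle(outdir=config.outdir)
    config.outdir.mkdir(parents=True, exist_ok=True)
    bundle.log.append("constants: " + json.dumps(asdict(config.constants)))
    for stage in config.stages:
        runner = _STAGE_RUNNERS[stage]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                table, record = runner(config)
            except AlbuminBindError as exc:
                raise type(exc)(f"stage {stage!r}: {exc}") from exc
        for w in caught:
            bundle.log.append(f"[{stage}] {w.category.__name__}: {w.message}")
        bundle.tables[stage] = table
        bundle.records[stage] = record
        _round_table(table).to_csv(config.outdir / f"{stage}.csv", index=False)
        with open(config.outdir / f"{stage}.json", "w", encoding="utf-8") as fh:
            json.dump(record, fh, indent=2, default=_jsonable)
            fh.write("\n")
    with open(config.outdir / "run.log", "w", encoding="utf-8") as fh:
        fh.write("\n".join(bundle.log) + "\n")
    return bundle


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
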