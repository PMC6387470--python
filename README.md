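# albuminbind

Analysis toolkit for characterising how a small-molecule drug binds human
serum albumin (HSA) — the plasma protein that carries most circulating
drugs — from optical spectroscopy. It is aimed at biophysics and
drug-discovery labs that run the standard multi-spectroscopic binding
workup: fluorescence-quenching titrations, temperature-dependent binding
thermodynamics, Förster resonance energy transfer (FRET), far-UV circular
dichroism (CD), chemical-denaturation stability assays, and esterase
(p-nitrophenyl acetate) inhibition kinetics.

## What it computes

| Stage | Model | Outputs |
|---|---|---|
| Quenching | F₀/F = 1 + K_SV[Q]; log₁₀(F₀/F−1) = log₁₀K_b + n·log₁₀[Q] | K_SV, k_q = K_SV/τ₀, K_b, n, static/dynamic call |
| Thermodynamics | ln K = −ΔH°/RT + ΔS°/R; ΔG° = ΔH° − TΔS° | ΔH°, ΔS°, ΔG°(T), dominant-force labels |
| FRET | J = ∫Fελ⁴dλ/∫Fdλ; R₀⁶ = 8.79×10⁻²⁵κ²n⁻⁴φJ; E = 1−F/F₀ = R₀⁶/(R₀⁶+r⁶) | J, R₀, E, donor–acceptor distance r, validity flags |
| CD | MRE = Θ/(10·n_bonds·C·l); %α = (\|MRE₂₂₂\|−2340)/30300·100 | MRE, helix %, change vs free protein |
| Unfolding | ΔG_D([g]) = ΔG_D° − m_g[g], two-state mixture of baselines | ΔG_D°, m-value, midpoint C_m, ΔΔG on ligand binding |
| Kinetics | v = V_maxS/(K_m+S) (+ competitive K_m,app) | K_m, V_max, k_cat, k_cat/K_m, inhibition mode |

Fitting follows a statsmodels-like pattern: build a model from data, call
`.fit()`, get a results object with estimates, standard errors, R² and a
`summary()` table. A seeded synthetic-data module draws from each stage's
forward model with known ground truth, so the whole pipeline is testable
without instrument data. Inputs are plain two-column text spectra and CSV
titration/kinetics tables.

## Worked example

Simulate triplicate-averaged quenching titrations at three temperatures
and analyse the 25 °C one:

```sh
$ albumin-bind simulate quench --seed 7 --out-dir sim
sim/titration_25C.csv
sim/titration_30C.csv
sim/titration_37C.csv

$ albumin-bind quench --titration sim/titration_25C.csv --temperature-c 25
{
  "temperature_K": 298.15,
  "K_SV": 16128.80426424408,
  "K_SV_se": 54.754377546482296,
  "k_q": 2790450564748.1104,
  "K_b": 16827.44054461531,
  "K_b_se": 455.92435980718193,
  "n_stoich": 1.0048111100423918,
  ...
}
```

The titration was generated with K_b = 1.6×10⁴ M⁻¹ and 1% lognormal
noise; the Stern–Volmer slope (1.61×10⁴ M⁻¹) and double-log binding
constant (1.68×10⁴ M⁻¹, n ≈ 1.00) recover it within the noise. The
apparent k_q ≈ 2.8×10¹² M⁻¹ s⁻¹ sits two orders of magnitude above the
diffusion-controlled ceiling (2×10¹⁰), the signature of a ground-state
(static) complex rather than collisional quenching.

Feed binding constants at several temperatures to the van't Hoff stage:

```sh
$ albumin-bind thermo --kb 1.6e4,1.4e4,1.2e4 --temps-c 25,30,37
van't Hoff fit (ln K_b vs 1/T)
============================================
parameter        estimate       std err
---------------------------------------
dH_cal_mol          -4389         191.3
dS_cal_molK         4.507        0.6298
---------------------------------------
rsquared     0.9981
nobs         3
============================================
{
  ...
  "dG_by_T_cal_mol": [-5732.4, -5755.0, -5786.5],
  "force_label": "hydrophobic, hydrogen bond / van der Waals (spontaneous)"
}
```

ΔH° ≈ −4.4 kcal/mol with ΔS° > 0: binding is spontaneous
(ΔG° ≈ −5.7 kcal/mol), entropically favoured (hydrophobic contacts
dominate) with an exothermic hydrogen-bond/van der Waals contribution.

The same analyses are available as library calls
(`albuminbind.fit_stern_volmer`, `vant_hoff_fit`, `FretAnalysis`,
`fit_two_state`, `fit_michaelis_menten`, ...), and `albumin-bind run
--config run.yaml` executes any subset of stages from a YAML config,
writing per-stage CSV/JSON tables and a run log.

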