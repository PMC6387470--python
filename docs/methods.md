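# Methods

`albuminbind` implements the quantitative analyses used to characterise the
binding of a small-molecule drug to human serum albumin (HSA) from optical
spectroscopy, together with seeded generators that draw synthetic data from
each analysis's own forward model. This note documents the models, their
assumptions, the defaults that matter, and what the synthetic tests do and
do not demonstrate.

## Spectral container and derivatives

Spectra are sampled signals on a strictly increasing wavelength grid in nm
(absorbance, fluorescence a.u., ellipticity in mdeg, or molar extinction in
M⁻¹ cm⁻¹; a signed `derived` kind holds differences and derivatives, which
legitimately go negative even when the parent kind cannot). Files are
two-column delimited text with `#` comments; values are written with
shortest-round-trip float formatting so write→read is bit-identical.

Second-derivative absorption spectra — used to resolve the overlapping
Phe/Tyr/Trp aromatic bands near 260/270/280 nm — are computed by
Savitzky–Golay filtering (default window 7 points, polynomial order 3).
The filter assumes a uniform grid; non-uniform grids are rejected rather
than silently resampled. Window and order are configurable because no
universal choice suits all instrument resolutions; 7/3 is the common
default for derivative UV spectroscopy at ~1 nm sampling.

Difference spectra are computed on the union of the two grids restricted
to their overlap, and classify the mean change in a caller-chosen window
(e.g. 270–290 nm) as hyper-/hypochromic with a tolerance of 1e-12 of the
signal scale, so exact equality reports "none".

## Fluorescence quenching and binding

The titration model is the ground-state-complex (static quenching) law
F = F₀ / (1 + K_SV[Q]). Analyses:

- **Inner-filter correction** F_corr = F_obs·exp((A_ex + A_em)/2), applied
  pointwise when the titration carries per-point absorbances at the
  excitation and emission wavelengths.
- **Stern–Volmer**: OLS of F₀/F on [Q]. The intercept is deliberately left
  free — it should be 1, and a deviation beyond 3 standard errors raises a
  warning as a diagnostic for residual inner-filter effects. The apparent
  bimolecular rate constant is k_q = K_SV/τ₀ with τ₀ = 5.78 ns (HSA Trp
  lifetime); this identity holds exactly by construction in every result.
- **Double-log binding**: OLS of log₁₀(F₀/F − 1) on log₁₀[Q] gives the
  stoichiometry n (slope) and binding constant K_b (10^intercept, base-10
  logs as in this literature). Points with F ≥ F₀ at nonzero quencher are
  excluded with a warning. The K_b standard error is delta-method
  propagated from the intercept.
- **Mechanism classification**: "static" requires K_SV strictly decreasing
  with temperature *and* every k_q above the diffusion-controlled ceiling
  (2×10¹⁰ M⁻¹ s⁻¹); "dynamic" requires the opposite on both counts;
  anything else is "indeterminate" with the failed criteria listed.

## van't Hoff thermodynamics

ln K_b is regressed on 1/T (least squares, not endpoint slope), assuming
the binding enthalpy is constant over the 25–37 °C range studied:
ΔH° = −R·slope, ΔS° = R·intercept with R = 1.987 cal K⁻¹ mol⁻¹. All
internal energies are cal/mol; kcal appears only at reporting layers,
avoiding silent J/cal unit mixups. ΔG°(T) = ΔH° − TΔS° is the primary
route; −RT ln K_b is provided as a cross-check (they agree only as well as
the K values obey the fitted line). Force classification follows the
standard sign convention: ΔS° > 0 → hydrophobic; ΔH° < 0 → hydrogen
bonding / van der Waals; ΔG° < 0 → spontaneous.

## FRET

The overlap integral J = ∫F(λ)ε(λ)λ⁴dλ / ∫F(λ)dλ is evaluated by the
trapezoidal rule with λ converted to cm, on a common grid at the finer of
the two native spacings; the acceptor extinction is zero outside its
measured range. With λ in cm the Förster relation R₀⁶ = 8.79×10⁻²⁵
κ²n⁻⁴φJ yields R₀ in cm (reported in nm), and J lands in the conventional
10⁻¹⁵ cm³ M⁻¹ range. J is invariant to donor amplitude (normalised form)
and to grid refinement within 0.1%.

Defaults κ² = 2/3 (isotropic dynamic averaging), n = 1.336 (aqueous
buffer) and φ = 0.118 (HSA Trp quantum yield) are the standard literature
values; all are configurable since published R₀ values are sensitive to
them (with these defaults and J = 3.08×10⁻¹⁵ cm³ M⁻¹, R₀ ≈ 2.0 nm).

Efficiency comes from intensities (E = 1 − F/F₀) and distance from the
inversion r = R₀((1−E)/E)^(1/6); the two routes E(intensity) and
E(R₀, r) can disagree when inputs come from different sources, so
`efficiency_consistency` compares them and warns beyond 0.05 rather than
choosing silently. Distance estimates are flagged valid when
0.5R₀ < r < 1.5R₀ and r lies on the 2–8 nm FRET scale.

## Circular dichroism

MRE = Θ_obs / (10·n_bonds·C·l) with Θ_obs in mdeg, C in mol/L, l in cm and
n_bonds = n_residues − 1 (584 for HSA), giving deg cm² dmol⁻¹. Helix
content uses the single-wavelength 222 nm estimator
%α = (|MRE₂₂₂| − 2340)/30300 × 100. The estimator is applied to the MRE
magnitude by default: helical MRE at 222 nm is negative and the formula
yields sensible percentages only on magnitudes (|MRE₂₂₂| ≈ 18,700
corresponds to the 54% helicity of free HSA). A sign-strict mode rejects
positive MRE instead. Values outside [0, 100] are clamped with a warning.
Full secondary-structure deconvolution is out of scope.

## Two-state chemical denaturation

The observed signal versus GdmCl molarity is fitted to the two-state
linear-extrapolation model: ΔG_D([g]) = ΔG_D° − m_g[g],
K = exp(−ΔG_D/RT), y = (y_N + y_D·K)/(1 + K), at 25 °C with
R = 1.987 cal K⁻¹ mol⁻¹. The sign convention (−m_g[g]) is the standard
one in which denaturant destabilises the native state and the midpoint is
C_m = ΔG_D°/m_g. Baselines are flat by default, with an optional
linear-in-[g] variant.

The objective is nonconvex, so fitting is multi-start: baselines from the
first/last 10% of points, C_m from the interpolated f_D = 0.5 crossing,
the m-value from a logit-line slope through the transition region, with
×0.5/×2 variations; the best converged start wins and total
non-convergence is a hard error with per-start diagnostics. C_m standard
errors use the delta method on the (ΔG, m) covariance block — C_m is
substantially better determined than its strongly anticorrelated factors,
a property the test suite asserts. Curves that do not put at least two
points in each baseline region (judged from the fitted transition) are
flagged.

## Esterase kinetics

v = V_max·S/(K_m + S) is fitted either by nonlinear least squares
(default; statistically preferred) or via the Lineweaver–Burk
double-reciprocal line (retained because published kinetic tables in this
literature derive from it); both report standard errors, the reciprocal
route via first-order propagation neglecting the slope/intercept
covariance. Units are fixed at mM and minutes. k_cat = V_max/[E] and
k_cat/K_m hold exactly for every fit. Inhibition classification compares
apparent (K_m, V_max) across doses against the zero-dose reference with a
10% relative "unchanged" tolerance: rising K_m with constant V_max is
competitive; falling V_max with constant K_m noncompetitive; both falling
uncompetitive; both constant "no inhibition"; anything else
mixed/indeterminate. A 2% change in V_max therefore classifies as
unchanged. K_i is not estimated (apparent-K_m classification only).

## Synthetic data: what it shows and what it does not

Each generator draws from exactly the model its analysis fits, with known
ground truth and a seeded `numpy` Generator (identical config ⇒
bit-identical output, including through CSV round-trips). Defaults are
the study's conditions:

- **Quenching**: K_b = 1.6×10⁴ M⁻¹, F₀ = 2546, 11 points over 0–250 µM so
  F₀/F spans ~1–5 (a double-log fit needs the transition spanned to pin
  the intercept); each intensity is the mean of 3 independent noisy
  trials, matching the triplicate protocol behind the published values,
  and the [Q] = 0 row is the exact reference by construction. Noise: 1%
  lognormal multiplicative. Optional absorbance columns grow linearly in
  [Q] and attenuate the signal so the inner-filter correction can be
  exercised end-to-end.
- **Band spectra**: Gaussian donor emission (340 ± 15 nm, peak 1 a.u.) and
  acceptor extinction (335 ± 25 nm, 4000 M⁻¹ cm⁻¹ peak) on a 280–420 nm
  grid, chosen to emulate the observed emission/absorption overlap and
  give J of order 10⁻¹⁵ cm³ M⁻¹.
- **Unfolding**: ΔG_D° = 4.92 kcal/mol, m = 1.98 kcal mol⁻¹ M⁻¹ (C_m
  2.48 M), MRE-like baselines −18700/−3000, 25 points over 0–6 M GdmCl;
  2% additive Gaussian noise scaled by the baseline separation.
- **Kinetics**: K_m = 0.348 mM, V_max = 10.2×10⁻⁴ mM/min, [E] = 8 µM,
  8 substrate points over 0.05–0.8 mM; competitive scheme
  K_m,app = K_m(1 + [I]/K_i) with K_i = 0.088 mM so the 1:5
  enzyme:inhibitor dose reproduces the published apparent K_m; 2%
  additive Gaussian noise. (The published 1:10 row is ~10% below the
  single-K_i prediction — real inhibition is rarely exactly single-site.)

Because the generators share their forward models with the fitters,
passing recovery tests demonstrates correctness of the estimation
machinery, not robustness to model misspecification: no baseline drift,
photobleaching, scattering, intermediate unfolding states or
substrate-depletion effects are simulated, and real instrument noise is
neither exactly lognormal nor exactly Gaussian.

## Numerical choices and limitations

- All OLS lines use `scipy.stats.linregress`; nonlinear fits use
  `scipy.optimize.curve_fit` (Levenberg–Marquardt or TRF with positivity
  bounds on ΔG and m).
- Monte-Carlo suite sizes (500 titrations, 200 unfolding curves, 500
  kinetics replicates, 1000 van't Hoff draws) keep the whole test run
  under ~10 s while giving stable medians.
- Temperatures are accepted in °C at interfaces and converted as
  K = °C + 273.15; all equilibrium math is in Kelvin.
- The Stern–Volmer and double-log analyses assume a single fluorophore
  class and pure static quenching; mixed static/dynamic quenching would
  curve the Stern–Volmer plot and is not modelled.
- The published quenching table contains one internal inconsistency the
  package intentionally does not reproduce: the 25 °C k_q entry does not
  equal K_SV/τ₀, while the 30 and 37 °C entries do. The package always
  reports the identity-consistent value.
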