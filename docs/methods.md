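# Methods

This note documents the models, conventions, calibrations and numerical
choices behind `fluorosel`, in the order of the analysis chain.

## 1. The synthetic trial generator

### What it emulates

A balanced multi-environment hybrid trial: 16 genotypes × 3 years ×
4 replicates in a randomized block layout (a second, orthogonal
blocking factor with 4 levels per year is assigned as
`(genotype_index + rep_index) mod 4`), with chlorophyll-*a*
fluorescence recorded on 3 plants per plot (576 plants) and plot-level
grain yield and grain moisture (192 plots). Plot weight and sample
moisture are back-computed from the generated GY/GM through the 14%
standardization formula

    GY(t/ha) = (W_kg · (100 − moisture%)/86 · 10000/area_m²) / 1000,

so the agronomic CSV round-trips exactly through the same constructor
used for real data.

### Fluorescence model

Each plant's induction curve is a phenomenological sum of three
saturating exponentials on a quasi-logarithmic 118-point grid from
20 µs to 1 s:

    F(t) = F0 + (Fm − F0) · Σ_k w_k (1 − exp(−t/τ_k)),
    τ = (0.3 ms, 8 ms, 120 ms),  w = (0.55, 0.25, 0.20).

The three time constants reproduce the O–J, J–I and I–P phases; the
curve is nondecreasing by construction, which is what the landmark
extractor assumes. No within-curve measurement noise is added: all
plant-to-plant variation enters through the kinetic parameters, so
generated curves are smooth. This is the main idealization relative to
instrument data (real exports carry correlated high-frequency noise and
occasional non-monotone segments near P), and it means passing tests
say nothing about robustness to such noise.

Biological effects act on two channels, both multiplicative on
log-scale because the affected quantities are positive and
ratio-scaled:

* **amplitude**: genotype/GxE/plant effects multiply L = log(Fm/F0);
  this moves F_v/F_m (and everything downstream of φ_Po);
* **shape**: effects multiply the O–J weight w₁ (weights renormalized
  to sum to 1); this moves V_J, M0 and hence ψ_Eo and PI_ABS with only
  a second-order effect on F_v/F_m.

Year base amplitudes L_year are solved (Brent's method) so that the
*expected* measured F_v/F_m — the expectation over both effect
channels, taken by 9-node Gauss–Hermite quadrature — equals the
configured year mean (0.803, 0.805, 0.810). Without the quadrature the
concavity of measured F_v/F_m in L leaves a bias of order 5·10⁻⁴.

### Effect scales and calibration

Agronomic effects follow y = µ_year + g_i + (gy)_ij + r_jk + b_jB + ε
with variances taken directly from the emulated study: GY
σ²_G = 0.553, σ²_GxE = 0.307, σ²_e = 2.593; GM σ²_G = 1.296,
σ²_GxE = 2.209, σ²_e = 0.795. Year means are fixed (not random), which
by itself reproduces the reported year variance components to within
~10%. The study reports a significant replication effect for yield but
prints no component for it, so the generator defaults to a small
nonzero σ²_rep(GY) = 0.10 (configurable), and a small block variance
for GM only, mirroring which block tests were significant.

Genotype effects of (latent photosynthetic amplitude, GY, GM) are drawn
from a trivariate normal whose correlation matrix carries the
genetic-correlation targets r_G(GY, F_v/F_m) = 0.35,
r_G(GM, F_v/F_m) = −0.61, r_G(GY, GM) = −0.10; the shape-channel
genotype effect is independent. Because the map from amplitude effect
to measured F_v/F_m is smooth and locally linear at these small effect
sizes, the correlation targets survive the nonlinearity.

The fluorescence effect standard deviations (defaults in
`FluorescenceEffects`) were fixed by a one-time calibration and then
frozen:

* amplitude channel σ_G : σ_GxE : σ_plant = 0.010 : 0.00926 : 0.02268,
  ratios chosen so the progeny-mean heritability of plot-mean F_v/F_m
  is ≈ 0.70 under the H² formula (1 : 0.857 : 5.14 on the variance
  scale, with the plant variance divided by 3 at plot level);
* shape channel 0.040 : 0.02191 : 0.05367 (variance ratios
  1 : 0.3 : 1.8), a channel-wise H² of ≈ 0.87, scaled so that the
  shape channel dominates PI_ABS variance and the realized H²(PI_ABS)
  is ≈ 0.84.

Replicate-trial checks (25 seeds) confirm realized H²(F_v/F_m) ≈ 0.70,
H²(PI_ABS) ≈ 0.84, year means within 2 Monte-Carlo SEs, and recovery of
the GY/GM generating components within 3 Monte-Carlo SEs.

Within-plot (plant-to-plant) fluorescence spread has no reported
counterpart; it is exposed as the free parameters
`amp_sigma_plant` / `shape_sigma_plant`.

## 2. OJIP landmarks and the JIP-test

Conventions (Handy-PEA style):

* F0 is the reading at the grid point nearest 50 µs — the standard O
  point; consequently F0 = F1. F1…F5 sit at 50 µs, 100 µs, 300 µs,
  2 ms (J) and 30 ms (I); lookups take the nearest grid point (no
  interpolation, tolerance one grid step, errors name the missing
  landmark).
* Fm is the curve maximum (first occurrence), t_Fm its time in
  seconds; the complementary area is the trapezoidal integral of
  Fm − F(t) from t(F0) to t_Fm.
* Kinetic quantities use the customary millisecond scale:
  M0 = 4 ms⁻¹ · (F300µs − F50µs)/(Fm − F50µs), Sm = area/(Fm − F0)
  in ms, N = Sm·M0/V_J. The "initial curve inclination" dV_G/dt0 is
  implemented as (F100µs − F50µs)/((Fm − F50µs) · 0.05 ms) — it is
  named but not defined in the source literature, so the definition
  here (slope of relative fluorescence over the first marker interval)
  is the package's own.

The parameter roster ships in two documented presets: the canonical
56-entry JIP-test set (`jip56`: landmark-derived raw quantities,
variable-fluorescence ratios, kinetic quantities, quantum
yields/probabilities, RC density, specific fluxes per reaction centre,
flux ratios per absorption, cross-section fluxes at F0 and Fm, and
performance indices PI_ABS, PI_total, SFI_ABS, driving forces) and
`extended58` which prepends the raw F0 and Fm signals — both counts
appear in the emulated study. The exact roster of the original
instrument software is not published, so one-to-one column
correspondence cannot be guaranteed; the ordering is fixed and
documented in `fluorosel.ojip.PARAM_NAMES_56`.

Undefined ratios (V_J ∈ {0,1}, φ_Po ∈ {0,1}, M0 ≤ 0, δ_Ro ≥ 1) are
emitted as NaN with a logged reason, never as infinities, so they
surface as missing values rather than corrupting the PLS stage.

Scale behaviour: all yield/probability/flux-ratio parameters are
invariant under a gain change F → cF (`SCALE_INVARIANT`); the V-based
kinetic subset is additionally invariant under the affine normalization
(F − F0)/(Fm − F0) (`AFFINE_INVARIANT`). Both lists are asserted by
property tests.

## 3. PLS1 and component selection

`NipalsPLS1` is a from-scratch NIPALS implementation for a single
response: deterministic (weights from X'y, no random initialization),
with mean centering always and unit-variance autoscaling as a flag.
The default policy follows the units of the predictor block:
biophysical parameters (heterogeneous units) are autoscaled, raw
transients (one fluorescence unit) are centered only. Coefficients are
kept for every component count 0…k (`coef_path_`), scores are
orthogonal to 1e−8 relative, and the rotation R = W(PᵀW)⁻¹ uses the
upper-triangular structure of PᵀW. When the deflated predictor block
is exhausted (‖Xᵀy‖ below 1e−12 of its initial value) extraction stops
with a warning and the effective component count is reported.

Cross-validation: rows (= plots; transient predictors are plot-mean
curves, so no plant-level leakage is possible) are partitioned into 10
seeded near-equal folds; RMSEP(k) is the root mean square of the pooled
out-of-fold residuals, not a mean of per-fold RMSEPs; RMSEP(0) reports
the per-fold mean model for reference. The selected component count is
the smallest k ≥ 1 attaining the minimum. The default component cap is
min(n − ⌈n/folds⌉ − 1, p). "Variance explained" is defined as
100·(Pearson r between observed values and the out-of-fold predictions
at the selected k)² — the source material frames it as a scatter of
observed versus predicted without a formula, so this definition is the
package's own and is stated wherever the number is reported. One
seeded CV split is used per run; repeated CV is available by calling
`cross_validate` with different seeds.

## 4. Variance components, heritability, selection efficiency

For the balanced layout the method-of-moments/EMS estimators are exact
and closed-form (see module docstring for the contrast formulas);
negative solutions are truncated at zero. On balanced tables without
truncation they agree with REML (cross-checked in tests against lme4
with year and rep-within-year fixed, genotype and genotype:year random,
to 1e−4 relative). The ANOVA models block as block-within-year with
e(b−1) = 9 df, matching the reported table structure; the rep(year)
stratum is estimated but not reported as a component in `varcomp.csv`,
mirroring the emulated study's tables.

Standard errors of H² and r_G use a delete-one-genotype jackknife (the
study prints ± values without naming a method; the jackknife is the
natural resampling unit for entry-mean quantities and its SE shrinks
~1/√g, which is asserted in tests). r_G is reported unclipped even when
|r_G| > 1 — single-trial genetic correlations of weakly heritable
predictions are extremely noisy and clipping would hide that — with a
warning attached.

EI = |r_G|·h_X/h_Y (×100) exactly as stated in the source formula.
Note the published EI percentages (38.86 / 92.41 / 86.89) are *not*
recoverable from the published r_G and H² values through this formula
(e.g. 0.97·√(0.50/0.64) = 0.862, not 0.9241); the package implements
the stated formula and reports self-consistent EI values rather than
reverse-engineering the printed ones. Every EI in `report.json` is
back-computable from the report's own r_G and H² fields to 1e−10.

Two further inconsistencies in the published component tables are
excluded from the worked-example checks: the observed-GY row computes
to H² = 0.63 against a printed 0.64, and the F_v/F_m row's printed
components give 0.18 against a printed 0.70.

Predicted traits enter the variance-component machinery as the
*cross-validated* (out-of-fold) predictions attached at plot level, so
their error variance reflects out-of-sample noise; in-sample fitted
values would inflate H² of the prediction. On replicate simulations
the EI for GY via transient predictions exceeds EI via the
few-component parameter model on average — a tendency of the study
configuration, not a per-seed guarantee, and it is documented rather
than asserted.

## 5. Problem sizes and determinism

All defaults run at the study scale (576 transients, 192 plots) in a
few seconds; the replicate-trial test ensemble uses 25 seeds. Every
random draw flows from explicit integer seeds (simulation and CV seeds
are separate and recorded in the report), and identical configuration +
seeds give byte-identical CSV/JSON artifacts, which the pipeline tests
assert.

## 6. Known limitations

* The fluorescence model is phenomenological: no photosystem II
  electron-transport kinetics, no connectivity/sigmoidicity in the O–J
  rise, no curve noise, no stress covariates; conclusions about the
  *statistical* pipeline transfer to real data, conclusions about
  biophysical fidelity do not.
* The generator's genetic coupling links GY/GM only to the amplitude
  (F_v/F_m) channel; the shape channel (PI_ABS) is genetically
  independent of agronomy by default, so simulated transient-based
  predictions gain their accuracy through the amplitude channel.
* Unbalanced tables are rejected rather than analyzed (no REML path in
  the package proper); spatial/row-column adjustments and
  multi-location structures beyond years are out of scope.
* Ingest mode accepts CSV exports only; proprietary binary instrument
  files are not parsed.
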