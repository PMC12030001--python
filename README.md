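# fluorosel

In-season indirect selection for maize breeding from chlorophyll-*a*
fluorescence.

Maize breeders want to rank hybrids for grain yield (GY, t/ha at 14%
grain moisture) and grain moisture at harvest (GM, %) *before* harvest,
ideally around flowering while crossing decisions can still be made.
A fast fluorometer reading on a dark-adapted leaf — the polyphasic
O-J-I-P induction transient — is cheap to collect on every plot and
carries information about photosystem II performance. `fluorosel`
implements the complete analysis chain that turns such measurements
into a selection decision:

1. **OJIP / JIP-test engine** (`fluorosel.ojip`) — parse 118-point
   transients, extract the O, J (~2 ms), I (~30 ms) and P (= F_m)
   landmarks, normalize by total variable fluorescence F_v = F_m − F_0,
   and derive the biophysical parameter set (quantum yields φ_Po = F_v/F_m,
   ψ_Eo, flux ratios, specific and cross-section fluxes, and the
   performance index PI_ABS = (RC/ABS)·[φ_Po/(1−φ_Po)]·[ψ_Eo/(1−ψ_Eo)]).
2. **PLS1 regression** (`fluorosel.pls`) — a from-scratch NIPALS
   estimator in scikit-learn style (`fit`/`predict`/`get_params`),
   with ten-fold cross-validation, the RMSEP curve, and latent-variable
   selection at the RMSEP minimum.
3. **Quantitative genetics** (`fluorosel.quantgen`) — balanced-design
   ANOVA, method-of-moments variance components (σ²_G, σ²_E, σ²_GxE,
   σ²_e), progeny-mean heritability
   H² = σ²_G / (σ²_G + σ²_GxE/n_E + σ²_e/(n_E·n_R)),
   genetic correlations r_G = Cov_G(X,Y)/(σ_G(X)·σ_G(Y)), Fisher's LSD,
   and the efficiency of indirect selection EI = |r_G|·h_X/h_Y.
4. **Synthetic trials** (`fluorosel.synthetic`) — a seeded generator for
   a balanced 16-hybrid × 3-year × 4-replicate trial with 3 plants
   measured per plot, calibrated year means and variance components,
   and genetic coupling between the latent photosynthetic genotype
   effect and GY/GM, so that the entire pipeline is testable without
   field data.
5. **Pipeline** (`fluorosel.pipeline`, CLI `fluorosel`) — orchestrates
   simulate/ingest → JIP tables → PLS models for GY and GM from both
   predictor blocks (biophysical parameters, raw transients) →
   variance components of observed and predicted traits → the
   indirect-selection-efficiency report.

## Worked example

```sh
fluorosel run --seed 1 --out-dir out
```

simulates the default trial, fits all four models, and prints (numbers
produced by this exact command):

```
Observed traits (variance components and heritability):
  gy     sigma2_G=0.3835  sigma2_GxE=0  sigma2_e=2.348  H2=0.66 +/- 0.23
  gm     sigma2_G=0.6071  sigma2_GxE=2.139  sigma2_e=0.7106  H2=0.44 +/- 0.28
  fvfm   sigma2_G=1.076e-05  sigma2_GxE=3.306e-06  sigma2_e=1.042e-05  H2=0.85 +/- 0.10
  piabs  sigma2_G=0.004297  sigma2_GxE=0.001106  sigma2_e=0.003035  H2=0.87 +/- 0.05

Prediction models:
  gy_parameters          LV=  3  RMSEP=2.045  var.expl=0.07%  H2=0.03  rG=1.66  EI=35.45%
  gy_transients          LV=  1  RMSEP=2.027  var.expl=2.65%  H2=0.43  rG=0.69  EI=55.82%
  gm_parameters          LV=  1  RMSEP=4.732  var.expl=2.57%  H2=0.87  rG=-1.07  EI=149.93%
  gm_transients          LV=  1  RMSEP=4.717  var.expl=3.15%  H2=0.77  rG=-0.74  EI=98.30%
```

Reading the output: each model row is one trait × predictor-block
combination. `LV` is the latent-variable count at the cross-validated
RMSEP minimum; `var.expl` is 100·r² between observed values and the
out-of-fold predictions; `H2` is the progeny-mean heritability of the
*predicted* trait treated as a phenotype; `rG` its genetic correlation
with the source trait (reported unclipped — single-trial estimates are
very noisy, which is why |rG| can exceed 1); and `EI` the efficiency of
selecting on the prediction relative to direct selection. Full tables
(`varcomp.csv`, `correlations.csv`, `selection_efficiency.csv`,
per-model RMSEP/coefficient/loading/prediction CSVs, `report.json`) and
optional figures land in `out/`.

The same analysis runs on real Handy-PEA-style CSV exports via
`mode: ingest` (see `fluorosel run --config`, `fluorosel jip`,
`fluorosel fit`, `fluorosel quantgen --help`).

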