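# Methods

## Overview

`telovasc` implements a cross-sectional analysis chain relating
leukocyte telomere length (LTL) to vascular phenotypes, together with a
synthetic-cohort generator that serves as its verification harness.
Every statistical claim the package makes about itself is computed by
its own tests or by `scripts/acceptance.py` at run time; nothing is
asserted from the literature.

## Exposures

**Measured LTL.**  Relative telomere content from qPCR, quantified per
plate by standard-curve interpolation: each target (telomere, albumin)
carries a seven-point curve of a reference DNA sample in twofold
dilutions (230 → 3.59 ng/µl); a well's quantity is
`Q = 10^((Ct − intercept)/slope)` and the per-well T/S ratio is averaged
over the triplicate.  Interpolation per target rather than the 2^−ΔΔCt
shortcut is used because a full curve is run on every plate; the two
coincide at 100% efficiency.  QC follows the standard rules: curve
efficiency `10^(−1/slope) − 1` within 90–110% and R² > 0.99; triplicates
excluded when the coefficient of variation of the Ct values (sample SD /
mean, n−1 denominator — a deliberate convention, as triplicates are
small samples) exceeds 1%; any amplification in a negative control gates
the whole plate.  Wells are paired by replicate index when forming
per-well ratios.

**Genetically predicted LTL.**  Weighted polygenic scores
`score_i = Σ_j w_j · d_ij` over effect-allele dosages `d ∈ [0, 2]`, one
score per instrument panel (sizes 150 / 130 / 47 / 20 by default).
Allele harmonization to the effect allele is a documented precondition
of the scorer, not a feature: dosage inputs must already be oriented.
The count of the Mendelian-randomization panel is configurable because
published descriptions of it disagree (130 in one place, 100 in
another); 130 is the default.

**ΔLTL.**  The OLS residual of measured LTL on [intercept, PRS, batch
indicator contrasts, PC1–10].  The raw residual is kept for diagnostics;
a z-standardized copy enters outcome models, consistent with the global
convention that all continuous analysis variables are z-scored.  By
construction ΔLTL is orthogonal to the PRS and to every PC
(|r| < 1e−8 is asserted on every generated cohort).

## Vascular phenotypes

Standard clinical formulas (see `telovasc.vascular`).  Two derivations
deserve comment:

* **SVRI** is computed as MAP/CI·80.  The resistance formula is often
  written with CO in the denominator, but the *index* units
  (dynes·sec/cm⁵ per m² body surface) and the magnitude of population
  means (~2100 with MAP ≈ 93 mmHg, CI ≈ 3.2) are only consistent with
  division by cardiac index.  A `svri_denominator="co"` switch restores
  the literal reading.
* **Composite vascular health index**: the average of the nine
  phenotype z-scores with SVRI, PWV, MAP and PP negated so that higher
  uniformly means better vascular health; `orient=False` reproduces the
  literal unsigned average.

The ABI side-selection rule (lower side if it is below 1.40, otherwise
the higher side) is implemented as written; when exactly one side is
≥ 1.40 the lower side is reported, which is one reading of an ambiguous
convention and is asserted in tests as this package's behavior, not as
the only possible one.

RSH windows are anchored to the protocol: baseline = first 2 minutes,
plateau = last 2 minutes of the 26-minute trace.  Traces are synthesized
at 1 Hz — the protocol does not fix a sampling rate, and window means
(all that RSH uses) are rate-invariant.

## Association models

One OLS per exposure × outcome with the family-specific covariate set
(measured: age, sex, LTL batch, BMI, smoking; PRS: age, sex, PC1–10,
BMI, smoking; ΔLTL: age, sex, BMI, smoking, matching-panel PRS).
Outcomes: the nine composite phenotypes plus SBP, DBP and the composite
index, which uses the same covariate families as single phenotypes (the
design leaves this open; identical treatment is the simpler choice).
Analyses are complete-case; 95% CIs use the normal approximation
β ± 1.96·SE (a t-quantile option exists); two-sided p-values come from
the t distribution; no multiple-testing correction is applied in this
battery because the exposure–phenotype hypotheses are specified a
priori (α = 0.05).  Interaction tests add an exposure×age (z-scored) or
exposure×sex term to the base model; sex-stratified fits are emitted
only when the sex interaction is significant.  A sensitivity variant
adds the 12 leukocyte subtype proportions (neutrophils, the largest
compartment, dropped as the reference against the sum-to-one
constraint) to the measured-LTL family.  Education is generated by the
cohort simulator but excluded from every default covariate set, since
no model family includes it.

## EWAS

Methylation (beta scale, as generated; an M-value switch is available
but off by default) is regressed CpG-by-CpG on the LTL measure with
covariates age, sex, batch, 11 cell proportions and PC1–10.  The
per-CpG fits are computed by projecting the covariates out of the
exposure and all CpG columns at once (Frisch–Waugh–Lovell), which is
algebraically identical to separate full fits and is verified against
statsmodels OLS to 1e−10.  BH step-up q-values are computed within each
exposure's scan (three separate FDR families, matching per-exposure hit
reporting); q < 0.05 is genome-wide significant, p < 1e−05 suggestive.
The single `batch` label plays the role of both the measurement batch
and the array batch — the generator makes no distinction.

## The synthetic cohort

The generator defines the study conditions; its defaults are fixed,
not tuning knobs.

* **Covariates**: age truncated-normal on [30, 95] and BMI
  truncated-normal above 14, each *moment-matched* so the realized
  (truncated) mean and SD equal the published summaries (55.5/14.0
  years, 25.8/4.4 kg/m²) — the summaries describe the observed data, so
  the parent distribution is solved for, not copied.  Sex Bernoulli
  (56.2% women), current smoking Bernoulli (12.2%), education
  12/43/45% (probabilities invented; education is never modeled), 8
  batches, PCs standard normal, 12 leukocyte proportions Dirichlet with
  a neutrophil-dominant concentration.
* **Genetics**: independent variants, MAF ~ U(0.05, 0.5), dosages
  Binomial(2, MAF).  Linkage disequilibrium, imputation and population
  structure are deliberately absent — the PRS is a weighted sum, and
  none of the regression contracts verified here depend on LD.
* **Latent LTL**: 0.14·PRS_z − 0.006·(age − 55.5) + 0.02·(woman) +
  residual, residual SD set to √(1 − var(systematic)) so the marginal
  SD is ~1.  Measured LTL is the latent value (the residual already
  stands for all non-genetic variation including measurement error);
  the qPCR channel maps it monotonically to a T/S ratio near 1
  (`exp(0.25·latent)`) and is verified separately.  Published cohort
  summaries report measured LTL as −1.0 (0.3), which cannot be a raw
  T/S ratio; the generator emits raw ratios near 1 and leaves that
  reporting-scale discrepancy documented rather than resolved.
* **Outcomes**: drawn on the z-scale as planted linear functions of the
  configured exposures and covariates, with noise completing the
  variance to 1 (empirically, per replicate).  Only seven phenotypes
  are free dimensions: MAP = SVRI·CI/80 and PP = SI/TACI are algebraic
  identities, so MAP, PP, SBP and DBP are induced, never planted — and
  the published per-phenotype summary means are themselves mutually
  inconsistent with those identities (2120 ≠ 92.6/3.2·80), presumably
  because the source data used beat-to-beat supine MAP for resistance.
  The induced BP level here (~116/69) is the price of exact internal
  consistency.
* **Raw-scale anchors**: each planted phenotype maps affinely to its
  raw scale at the published mean.  The RSH and PWV raw SDs are
  narrowed (150 vs 492; 1.5 vs 2.9) because with the published spreads
  a symmetric marginal puts 11% (RSH) / 1% (PWV) of draws outside
  physical support; rejecting those draws would truncate the
  distribution and attenuate every planted z-scale coefficient by up to
  ~17%, breaking the recovery contract the generator exists to serve.
  The real data are strongly right-skewed instead — a shape this
  generator does not model (see Limitations).  Non-physical draws are
  still rejected and redrawn (bounded attempts) so wide user-supplied
  scales remain safe.
* **Back-construction**: raw signals are solved from the planted
  derived values (SV = SI·BSA, HR = 1000·CI/SI, plateau flow from RSH,
  BP readings whose 2nd/3rd mean is exact, per-side ankle/arm pressures
  that make the ABI rule return the target, transit time from PWV), so
  the vascular derivations invert the generator to 1e−9 relative error
  — an exactness property the round-trip tests rely on.  Forward
  biophysical simulation was rejected deliberately: it would make
  planted effects uninterpretable on the z-scale the models report.
* **Methylation**: beta = logistic(latent), latent = intercept + sparse
  cell-type loadings + effect·exposure (causal CpGs) + N(0, 1) noise.
  The logistic keeps betas strictly in (0, 1) without asserting a
  marginal distribution the design never states.
* **Seeding**: every component draws from a named substream of the
  single master seed, so identical configs give byte-identical tables
  and adding draws to one component never perturbs another.

## Calibration and recovery

Preset scenarios carry the standardized effects the design is
calibrated to — measured LTL: +0.20 (RSH), +0.19 (CI), −0.13 (SVRI);
PRS: +0.04 (CI) and 0.14 on measured LTL itself; ΔLTL: +0.07 (RSH),
+0.08 (CI), −0.06 (SVRI) — one exposure family per scenario so each
coefficient is identifiable by its own model.  `telovasc.recovery`
regenerates 300 cohorts per design (n = 1828 or 4180), refits the exact
model, and requires the mean estimate within ±0.01 of the planted value
with 95% ± 3% CI coverage.  Problem sizes (300 replicates, 250 null
cohorts × 12 outcomes for type-I calibration, one 5000-CpG null scan)
were chosen to put the Monte-Carlo SE of each checked quantity at a
quarter or less of its tolerance.

## Numerical choices

OLS via statsmodels (QR-based), cross-checked in tests against the
closed-form normal equations to 1e−8.  BH step-up is implemented
directly (sorted cummin, stable sort for ties) and checked against both
an exhaustive-definition oracle and statsmodels' `fdr_bh` to 1e−12.
Zero-variance vectors error loudly in `standardize` rather than
returning silent zeros; constant CpG columns are skipped with a
warning; rank-deficient designs raise.  Trace window noise is recentered
within each window so window means are exact to floating point.

## Limitations

* The generator is a linear-Gaussian world: no skewed phenotype
  marginals (real RSH is strongly right-skewed), no LD, no
  batch-confounded methylation, no missing data (all analyses are
  complete-case on complete tables), no cell-type–LTL correlation
  beyond what users plant.  Passing recovery tests therefore
  demonstrates correctness of the estimators and plumbing under the
  stated conditions, not robustness to real-data pathologies.
* Planted effects on blood-pressure outcomes are structurally
  impossible (they are induced quantities here); the design plants none.
* The ABI ambiguity at exactly one side ≥ 1.40 and the measured-LTL
  reporting-scale discrepancy are documented, not resolved.
* External annotation (EWAS catalogs, gene-set enrichment, pathway
  analysis) and formal Mendelian-randomization estimators are out of
  scope.
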