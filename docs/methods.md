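# Methods

This note records the models, conventions and design choices behind
`herbenergy`, in the order a user meets them: the energy framework, the
equation registry, the REML development engine, the validation statistics,
the synthetic-trial generator, and the numerical details.

## Energy framework and units

A digestibility trial feeds a sheep a weighed herbage ration at the
maintenance level and partitions the gross energy (GE) of the intake:

    GE = fecal energy + urine energy + methane energy + ME
    DE = GE − fecal energy          (digestible energy)
    ME = DE − urine energy − methane energy   (metabolizable energy)

all expressed per kg of herbage dry matter (MJ/kg DM). Energy digestibility
GED = DE/GE. The chemical predictors are nitrogen (N), neutral and acid
detergent fibre (NDF, ADF), ether extract (EE), ash and GE; the
digestibility predictors are DMD, OMD, ND, NDFD, ADFD, GED and DOMD
(digestible organic matter per unit DM, DOMD ≤ OMD). Crude protein is
CP = 6.25 × N, and the total digestible quantities are
tdCP = CP × ND and tdNDF = NDF × NDFD.

Internally every mass fraction is stored as kg/kg DM, energies as MJ/kg DM
and digestibilities as fractions. Published tables quote the same
quantities in g/kg DM or % DM; conversion happens only at two boundaries —
file I/O and per-term equation units — and is an exact linear rescaling.

## Equation registry

Each prediction equation is stored with its response, intercept, ordered
terms, per-term unit, standard errors and provenance, and evaluated as

    ŷ = a + Σ_j b_j x_j

after converting each predictor into the term's declared unit. Evaluation
refuses records that cannot supply a predictor, and is exactly linear in
each predictor.

Three transcription conventions needed a decision, each resolved by
evidence and documented in the affected rows' `notes`:

- **Total digestible quantities (tdCP/tdNDF rows).** The table footnotes
  say g/100 g DM with CP = 6.25 N, but under that reading the equations
  evaluate far outside the response's own printed range at the study-mean
  record. The coefficient magnitudes are only consistent with total
  digestible quantities in g/kg DM with the nitrogen column taken at face
  value (the printed "N" column, 35–124 g/kg DM, is itself plausibly
  already crude protein). Those rows therefore declare unit `g/kg` with
  basis `printed_n`.
- **Literature rows containing CP.** The same reasoning applies: rows whose
  predicted means only reproduce under CP ≡ printed-N carry basis
  `printed_n`; one row is only consistent with % DM units and is stored
  that way. One literature row is printed with a positive fibre
  coefficient that would put ME above 27 MJ/kg at any plausible NDF; the
  negative sign (which reproduces the row's own printed predicted mean) is
  stored, with the printed form quoted in the notes. A row published in
  Mcal-based form is stored algebraically expanded to an affine equation
  in DE.
- **Anomalous rows.** Four whole-data rows (ids 2g, 2m, 3c, 4d) evaluate
  outside the printed min–max range of their own response at the
  study-mean record, while their two-thirds refit counterparts land
  comfortably inside — almost certainly misprints (an intercept sign or
  digit). They are transcribed exactly as printed and carry
  `anomaly = True`; the pipeline surfaces a warning when they are used.
  Nothing is silently corrected.

Registry contents are frozen by SHA-256 checksums asserted in the tests.

## Equation development (REML)

Equations are developed as linear models with candidate random intercepts
for the trial structure:

    y = Xβ + Σ_k Z_k u_k + e,   u_k ~ N(0, σ² γ_k I),  e ~ N(0, σ² I)

Fitting profiles the restricted likelihood over the variance ratios γ_k:
for fixed γ the GLS coefficients and σ̂² are closed-form, and the
deviance (−2 restricted log-likelihood)

    d(γ) = (n−p)(log 2πσ̂² + 1) + log|W| + log|X′W⁻¹X|,  W = I + Σ γ_k Z_k Z_k′

is minimised by L-BFGS-B over γ ≥ 0 from the corners of the unit box plus
an interior start. Because the zero corner is always a feasible start, the
full model's optimised deviance never exceeds a nested reduction's beyond
optimiser tolerance. Three further rules:

- **Aliased components.** A factor with one observation per level (each
  sheep is measured once in this design) satisfies Z Z′ = I, so its
  component is exactly absorbed by σ² and is held at zero rather than
  optimised. This mirrors the design reality: a per-animal variance is not
  estimable from single observations.
- **Parsimony tie-break.** After optimisation, any ratio whose removal
  costs ≤ 1e-8 deviance is set to zero, so degenerate limits reduce to OLS
  exactly (with classical OLS standard errors).
- **Backward elimination.** `develop_equation` fits all candidates, then
  repeatedly drops the component whose removal is least significant by the
  deviance χ² test until every survivor is significant at α = 0.05, and
  packages the fixed coefficients as a registry equation. A plain χ²
  reference is used despite the boundary at zero; the test is conservative
  (the null simulations in the test suite measure a rejection rate far
  below nominal), which is accepted and documented rather than corrected.

Fixed terms are tested by the Wald statistic (estimate/SE)² against χ²(1);
R² is the squared Pearson correlation of response and fitted values.
Deviances are comparable only between fits sharing the same fixed model
and data. Season and year enter as separate intercepts by default; a
combined trial factor is also supported.

## Validation statistics

- MSPE = (1/n) Σ (P − A)²; **MPE = √MSPE / mean(A)**. The square root is
  deliberate: it is the standard MSPE-technique definition, is
  dimensionally consistent with prediction errors of 1–8 % against
  residual SDs of 0.4–1.0 MJ/kg, and scale-invariant.
- Lin's concordance R_c = 2 cov(P,A) / (var(P) + var(A) + (mean P − mean A)²)
  with population (1/n) moments, so |R_c| ≤ |r| holds exactly with
  equality iff means and variances agree.
- The report's SE column is the standard error of the paired differences
  P − A (the natural uncertainty of the mean bias); residual summaries use
  the sample (n−1) SD.
- The internal split is trial-stratified: each trial contributes its
  proportional share (6 sheep → 4 development, 2 evaluation), preserving
  seasonal balance between subsets; it is random, seeded, and defaults to
  a fixed seed so replicas are reproducible. Display rounding follows the
  study conventions (MPE to 3 decimals, fold ratios to 1).

## Synthetic-trial generator

No per-sheep data accompany the study, so the generator is the package's
ground truth. It emulates the design — 11 trials × 6 sheep over June,
August and December of 2011–2016 — and the documented seasonal quality
gradient, via one latent "herbage quality" score per trial that moves
composition and digestibility together (N, EE, GE and all digestibilities
load positively; DM, NDF, ADF and ash negatively). Herbage composition is
drawn per trial (all six sheep of a trial eat the same herbage);
digestibilities vary per sheep around the trial mean through a per-sheep
ability score plus assay noise.

Anchoring: season means are set so their trial-plan-weighted average
reproduces the study-scale mean of every variable, and all means lie
inside the printed extremes. Draws are truncated normals with bounds equal
to the printed ranges widened by 20 % (composition) or 10 %
(digestibilities and GE — tighter so that the *derived* DE, ME, DOMD and
ratio columns stay inside the 20 %-widened printed bands by construction).
Truncation is a documented deviation from exact normality; the bias it
introduces in the means is kept below Monte-Carlo resolution by placing
every season mean ≥ ~2.2 SD from its bound.

The energy balance is built exactly (DE = GED × GE; urine and methane as
truncated-normal fractions of DE, means 0.045 and 0.097 so that mean
ME/DE = 0.858, the ratio of the study's printed mean ME to mean DE), then
measurement noise is added to the *measured* GE-digestibility and DOMD
columns only. That reproduces the small DE/GE-vs-GED discrepancy real
assays show while keeping ME < DE and the conservation identity exact in
the underlying balance. DOMD is constructed as OMD × (1 − ash) plus
bounded noise small enough that DOMD ≤ OMD always holds.

For parameter recovery, `generate_from_equation` overwrites a response
column with a registry equation's value plus configurable group-level
random effects and residual noise; the energy balance is intentionally not
rebuilt in that mode.

What the generator does **not** emulate: intake-level effects on
digestibility, within-trial day-to-day herbage variation, correlated assay
errors across nutrients, animal covariates (weight, age), or any
mechanistic rumen model. Passing tests therefore demonstrate that the
statistical machinery recovers known structure under the study's design
and noise scale — not that the printed coefficients are themselves
reproducible, which would require the original records.

## Problem sizes and numerical choices

- Parameter recovery uses 200 replicate datasets of n = 66 with residual
  noise set from the printed response SD and R² (e.g. 2.15 × √(1−0.806)
  for the DMD form); coverage of ±3 SE is required in ≥ 95 %.
- Wald calibration uses 1000 null replicates at n = 66 (expected empirical
  size ≈ 0.05 within [0.03, 0.07]); deviance-test power uses 200
  replicates with a season variance of 4 (MJ/kg DM)² — "large" because
  only three season levels carry the information — and 500 null
  replicates for conservatism.
- Optimiser: L-BFGS-B, bounds [0, 1e7], ftol 1e-10, ≤ 500 iterations,
  corner multi-starts (≤ 2^K + 1 for K free components). σ̂² is floored at
  1e-12 so an exactly collinear response cannot produce a degenerate
  log-likelihood. Fitting is fully deterministic given the data.
- Rank deficiency is reported with the names of the collinear columns;
  refusal, not silent dropping.

## Known limitations

- Variance-component p-values are conservative (boundary issue); with only
  3 season or 5 year levels the components are weakly identified, and the
  backward elimination will often drop genuinely small effects.
- The four anomalous registry rows evaluate outside their response's
  printed range by construction; consumers should prefer their refit
  counterparts (O, U, Z, AI).
- MPE requires a positive actual mean and is intended for concentration
  scales, not for residual-centred quantities.
- The generator's single-latent-quality design reproduces marginal ranges
  and the seasonal confounding, but real herbage covariance structure is
  richer; external validity of any tuned threshold should be established
  on measured data.
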