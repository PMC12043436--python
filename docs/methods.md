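# Methods

## Model and procedure

`mrscreen` implements a bidirectional two-sample Mendelian randomization
(MR) screen linking two families of molecular traits — immune-cell
phenotypes and circulating inflammatory proteins — to a binary disease
outcome, followed by two-step mediation and multivariable adjustment.
Only GWAS summary statistics are consumed; the three standard MR
assumptions (relevance, independence from confounders, exclusion
restriction) are taken as the inferential model, with sensitivity
diagnostics quantifying departures from the third.

**Instrument selection.** For each exposure, variants with p < 1e-5 are
candidate instruments. Greedy LD clumping then retains approximately
independent index variants: repeatedly take the remaining variant with
the smallest p, and discard every remaining variant on the same
chromosome within 10,000 kb *and* with r² ≥ 0.001 against it. Ties on p
break by (chromosome, position, rsid), which makes the output invariant
to input row order. LD is consumed as a precomputed sparse r² matrix;
no reference panel is needed.

**Harmonization.** Outcome associations are aligned to the exposure's
effect allele: identical allele pairs are kept (sign-flipping swapped
orientations), non-palindromic strand complements are complemented
first, and palindromic (A/T, C/G) variants are resolved by allele
frequency — dropped when either study's frequency is missing (default)
or falls in the intermediate band [0.42, 0.58), otherwise oriented by
whether the two frequencies sit on the same side of 0.5. The band and
the missing-frequency policy are configurable because published screens
vary in both; the defaults are the conservative end of common practice.
No LD-proxy lookup is attempted for instruments absent from the outcome;
they are dropped and counted.

**Estimators.** With per-SNP exposure/outcome effects (βx, βy) and
outcome standard errors σy:

- *Wald ratio* (1 instrument): βy/βx, se σy/|βx| (first-order).
- *IVW*: zero-intercept weighted regression of βy on βx, weights 1/σy².
  Default standard errors use multiplicative random-effects scaling
  max(1, √(Q/(k−1))); a fixed-effect variant is available. k = 1 reduces
  exactly to the Wald ratio.
- *MR-Egger*: the same regression with a free intercept, after orienting
  all βx positive. The slope is the pleiotropy-robust estimate; a
  nonzero intercept is the directional-pleiotropy test. Inference uses
  t with k−2 df and the same multiplicative scaling floored at one. The
  floor makes the intercept test mildly conservative when residuals are
  underdispersed (observed type-I ≈ 0.02–0.04 at α = 0.05), which we
  accept in exchange for never reporting a tighter-than-homoscedastic se.
- *Weighted / simple median*: order per-SNP ratios, place each at its
  cumulative weight minus half its own (normalized), and interpolate at
  1/2; weights are the inverse first-order ratio variances βx²/σy²
  (uniform for the simple median). Standard errors come from a
  parametric bootstrap (default 1,000 replicates) resampling βx and βy
  from normal(β, se); the bootstrap seed is part of the pipeline
  configuration so every run is reproducible.
- *Heterogeneity*: Cochran's Q over per-SNP ratios with the same
  first-order weights — algebraically identical to the IVW residual sum
  of squares — with I² = max(0, (Q−df)/Q) and the 25% / 50% labels
  (absent / mild / present).

First-order weights throughout mean exposure-side uncertainty is ignored
in weighting; this is accurate for strong instruments and is the
assumption the calibration suite verifies.

**Multiplicity.** The IVW p drives significance. The Bonferroni
threshold is 0.05 divided by the number of trait families (two by
default, so 0.025); BH FDR is applied per family by default (pooling is
a flag) because the two families are analysed as distinct screens.
Tiers: `bonferroni_significant` passes both the threshold and FDR,
`fdr_significant` passes FDR only, `marginal` passes the threshold but
fails FDR, `null` otherwise. Lowering the FDR level can only move a
pair down this ordering.

**Mediation.** For a triple (exposure X, mediator M, outcome Y) whose
three IVW legs are each significant at p < 0.05, the proportion mediated
is θ = β1β2/β0 with β0 the total X→Y effect, β1 the X→M effect and β2
the M→Y effect. The effect is *complementary* when the indirect effect
β1β2 shares the sign of β0 and *competitive* otherwise; a zero indirect
effect is labelled complementary with θ = 0 and p = 1 by convention.
The CI is a first-order delta-method interval on the three-parameter
ratio, treating the three estimates as independent (they come from
non-overlapping GWAS) — an approximation, since β0 and β1 share
instruments. The p-value is the Sobel-type normal test of β1β2 with
variance β1²se2² + β2²se1². Both conventions are this package's own
choices among the several used in the applied literature; the delta
interval is anti-conservative for very noisy β0.

**MVMR.** Instruments are the union of each exposure's clumped set,
re-clumped jointly ranking by the minimum p across exposures, restricted
to variants present and harmonizable in every table, then fit by
zero-intercept weighted multiple regression (weights 1/σy²) with the
same floored multiplicative covariance scaling — so a single-exposure
fit reproduces univariable IVW exactly. Exposures whose aligned effects
are all exactly zero are pinned to β = 0 with infinite se; genuinely
collinear exposures are a hard failure. Variants missing from any
exposure are dropped rather than zero-imputed (conservative).

**Reverse MR.** Direction `both` re-screens outcome→trait for every
forward pair with raw IVW p < 0.05, reusing the same instrument
threshold (configurable separately), mirroring the convention of
following up only screened-in pairs.

## Synthetic data generator

The generator emulates the three GWAS families at their real cohort
sizes — 3,757 individuals for the quantitative immune phenotypes, 876
for the protein mediators, and 1,881 cases / 391,037 controls for the
outcome, whose noise uses the effective size 4/(1/n₁+1/n₀) ≈ 7,485 on
the log-odds scale. Summary statistics are simulated directly on the
effect scale (two-sample MR never sees genotypes): each trait draws
sparse instrument effects γ ~ N(0, σ²) at a fraction π = 0.004 of the
panel, causal paths propagate effects downstream (SNP effect on Y =
own γ + Σ upstream total effect × upstream γ), true marginal effects are
smeared within LD blocks through the signed correlation matrix, and
observed β = truth + N(0, se) with se = 1/√(2n·eaf(1−eaf)). Stored
p-values are exactly the two-sided normal tails of β/se.

Default conditions: a 5,000-variant panel in exchangeable LD blocks of
10 (within-block r = 0.6), 30 exposures and 5 mediators as scaled-down
stand-ins for the 731-phenotype and 70-protein families, 20% palindromic
variants, per-file allele-label swaps (30%) and strand relabelling (10%)
with truth recorded. Exposure instrument scale σ = 0.2; mediators get
σ = 0.5 because protein GWAS report large per-variant (cis) effects
despite small cohorts — without this, an n = 876 study would yield
almost no instruments at p < 1e-5, which is realistic but would leave
the mediation stages untestable. Planted effects θ_xy = 0.15,
θ_xm = 0.3, θ_my = 0.15 (log-OR magnitudes in the OR ≈ 1.06–1.2 range
typical of trait screens) give a true mediation proportion
θ_xm·θ_my/(θ_xy+θ_xm·θ_my) = 23.1%.

Instruments are drawn block-exclusively: LD blocks are partitioned among
traits and each trait's instruments live only in its own blocks. Shared
or linked instruments across traits would constitute correlated
pleiotropy by construction and destroy null calibration; here pleiotropy
enters only through the explicit knob (`none`, `balanced`,
`directional`), which adds instrument-level outcome effects at the
mediated exposure's instruments. Consequences for interpretation:
passing tests show the pipeline is correct and calibrated when the MR
assumptions hold and instruments are strong; they do not probe winner's
curse, sample overlap, assortative mating, real minor-allele-frequency
spectra, or pervasive correlated pleiotropy, none of which the generator
emulates.

## Numerical choices and degenerate inputs

- p-values are floored at 1e-300; summary files store 10 significant
  digits, enough that rewriting a previously written table is
  byte-identical.
- Below-minimum instrument counts (1 for IVW/ratio, 2 for Q, 3 for
  Egger and medians) raise a structured `InsufficientInstruments`
  condition that the pipeline records as a withheld method — never a
  silent omission; a failed pair aborts only that pair.
- Median interpolation returns the extreme ratio when more than half the
  weight sits on it from either end; bootstrap draws of βx that hit
  exactly zero are nudged to the smallest positive float.
- Clumping with r² threshold 1 and window ~0 returns its input;
  self-screens (same trait as exposure and outcome) are refused.
- CI multipliers: normal 1.959964 everywhere except MR-Egger (t, k−2).

## Problem sizes

The test suite and the acceptance script scale the Monte-Carlo work to
desk size as the package's own defaults: estimator calibration uses 200
replicates of 50 instruments, the pleiotropy type-I check 500
replicates, the global-null screen 30 exposures on a 3,000-variant
panel, and the analysis scripts one 5,000-variant, 36-trait study.
These sizes give Monte-Carlo standard errors comfortably below the
effect sizes being verified.

## Known limitations

No weak-instrument (F-statistic) screening, Steiger directionality,
MR-PRESSO, or LD-proxy lookup; mediation treats the three legs as
independent; the binary outcome stays on the log-odds scale (no
liability-scale conversion); positions are GRCh37 with no liftover; and
empirical results from real cohort downloads are out of scope — the
package's claims are about correctness and calibration on known-truth
data, not about reproducing any particular cohort's odds ratios.
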