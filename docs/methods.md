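# Methods

## Data model

The pipeline's substrate is a long-format table of replicate-level
observations: one row per genotype × replicate × treatment × trait, with a
closed trait vocabulary (PRL, TRL, TSA, ARD, TRV, TRT, RF, SDW, RDW, TDW,
RSR, PCONC) and two derived efficiency quantities (PUPE, PUTIE) that exist
only at the genotype-mean level. Units are carried as metadata and never
converted: all computation treats values as unitless nonnegative reals,
because published unit labels for such screens are frequently inconsistent
(surface areas printed as cm² and cm³ interchangeably) and no statistic
here mixes traits additively.

Treatment labels are canonicalized to SP/LP with a built-in HP→SP alias
(both spellings denote the sufficient-P arm in the field); additional
aliases can be supplied at ingest. The key (genotype, replicate,
treatment, trait) must be unique; duplicates, negative or non-numeric
values, and unknown codes are hard errors. Missing cells are never
imputed: genotype means carry explicit NaN, correlations use
pairwise-complete deletion with the effective n reported per pair, and
each downstream stage reports or skips what it cannot compute.

Expected replicate count is r = 3 (the usual container design: each
genotype grown in triplicate per arm), but any balanced r ≥ 2 is accepted.
Unbalanced tables are fine for descriptive statistics and are refused by
the ANOVA operations, which assume balance; the error message says to
balance or subsample rather than silently switching estimator.

## Synthetic cohorts

The generator draws from the additive random-effects model

    value(i, t, k) = mu_t + G_i + GT_it + eps_itk

with G_i ~ N(0, σ²G) jointly across traits through a genotypic correlation
matrix (identity by default), GT_it ~ N(0, σ²GE) and eps ~ N(0, σ²e). TDW
is emitted as SDW + RDW and RSR as RDW/SDW per replicate, so the additive
consistency check passes by construction. Tissue P concentration is one
draw per genotype × treatment (repeated across replicates, as P is
measured on pooled tissue), which makes P uptake efficiency derivable.

Defaults emulate the published 85-genotype × 2-treatment × 3-replicate
lentil screen. Treatment means are the published per-trait panel means.
The printed genotypic-variance components themselves are not usable as
generative defaults: for several traits they imply a genotypic SD larger
than the low-P mean, and a normal model at those settings would clamp
10–20% of draws at zero. The defaults are therefore calibrated to the
published means and heritability magnitudes only: σ_G = 0.12 × pooled
trait mean (a 12% genotypic CV, typical of dry-mass traits in diversity
panels), σ²e backed out of the published single-condition heritability
(averaged over arms and clipped to [0.5, 0.9]) via σ²e = r·σ²G(1/H − 1),
and σ²GE set from the published interaction-to-genotype variance ratio
clipped to [0.2, 1.0]. Under these defaults the probability of a negative
draw is ≤ ~0.05% per trait; negative draws are clamped to 0 and counted in
a warning.

Reproducibility: one master seed; each (trait, channel) pair gets a
deterministic substream keyed by the trait's position in the closed
registry, so adding a trait to a config does not perturb the other traits'
draws. Correlated genotypic effects use a Cholesky (or eigenvalue, if
singular) factor of the correlation matrix applied to the per-trait base
draws; with a lower-triangular factor, appending a trait leaves earlier
traits' effects unchanged.

What the generator does **not** emulate: skewed or heavy-tailed trait
distributions (real root-count traits are strongly right-skewed),
species-level structure beyond a label column, heteroscedasticity across
genotypes, and any genuine biology linking P concentration to biomass.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to real-data pathologies.

## Variance components and heritability

Mean squares come from OLS fits (statsmodels `anova_lm`); on balanced data
these reproduce the classical sums-of-squares decomposition exactly, which
the test suite verifies against an independent explicit-loop oracle.
Method-of-moments solving of the expected-mean-square relations is done in
this package:

* single arm: σ²G = (MS_G − MS_E)/r, σ²e = MS_E;
* combined (genotype random, P level fixed, e = 2):
  σ²e = MS_E, σ²GE = (MS_GE − MS_E)/r, σ²G = (MS_G − MS_GE)/(r·e), with
  F_G = MS_G/MS_GE and F_GE = MS_GE/MS_E.

Negative moment estimates are truncated at 0 and logged. Mean squares that
are numerically zero (below 1e-10 times the squared data scale, i.e. OLS
round-off on noiseless data) are snapped to exactly 0 so degenerate inputs
yield exact degenerate outputs. Significance annotation follows the
convention of component tables in this literature: `**` at p < 0.01, `ns`
otherwise. No REML: the designs in scope are balanced, where the
method-of-moments solution is the ANOVA estimator.

A point worth stating explicitly: within a single P level the genotype
effect is G_i + GT_it, so the single-arm ANOVA estimates the confounded
variance σ²G + σ²GE, and the single-arm H estimates
(σ²G + σ²GE)/(σ²G + σ²GE + σ²e/r). The Monte-Carlo recovery study
(`lenspue.validation.heritability_recovery`) targets that estimable
quantity (0.75 under its defaults σ²G = 2000, σ²GE = 500, σ²e = 2500,
r = 3) and checks unbiasedness of the combined-model components by
averaging estimates over cohorts: per-cohort interaction estimates have
~35% sampling SD at 85 genotypes, which is expected behavior of the
estimator, not error. Study sizes (200 cohorts of 85 × 2 × 3) were chosen
as the smallest giving stable Monte-Carlo means.

## Descriptive statistics, correlations, PCA

Summaries operate on genotype means. CV% defaults to the genotype-mean CV
(100 × sample SD / mean, n−1 denominator), computable without balance; a
`residual` mode gives 100·√MS_E/grand-mean instead, since published CV
columns do not always say which basis they use. Percent change is
100·(x̄_LP − x̄_SP)/x̄_SP, signed so that reductions under low P are
negative (matching how such tables print reductions); "percent reduction"
in prose is the magnitude of a negative change.

Correlations are Pearson over genotype means with two-sided p from
t = r√((n−2)/(1−r²)); star annotation at 0.05 (`*`) and 0.01 (`**`).

"Relative values" are defined here as 100·LP-mean/SP-mean per genotype per
trait; the TDW column of that frame is then identical to PutiE, which ties
the PCA input to the efficiency definitions. PCA standardizes columns
(zero mean, unit sample variance) and eigendecomposes the correlation
matrix — appropriate for traits with heterogeneous units. Signs are fixed
so each loading vector's largest-magnitude entry is positive; scores are
the standardized data projected on the loadings, so their sample
covariance is diagonal with the eigenvalues. No rotations.

## Efficiency indices

PupE multiplies tissue P concentration (mg/g, as measured by digestion +
spectrometry) by dry matter (mg). The plain product is reported, on the
conventional scale of this assay's published tables (numerically µg per
plant though customarily labeled "mg plant⁻¹"); no hidden unit factor is
applied, so a concentration of 1.269 mg/g at 210 mg dry matter gives
266.49. Dry matter is TDW (the index literature uses total dry mass
throughout). PutiE = 100·TDW(LP)/TDW(SP) is one value per genotype and is
not clipped above 100.

The stress-index set uses GMPI = √(C·T) (the geometric-mean productivity
of the index literature, and the only reading satisfying the
HMI ≤ GMPI ≤ MPI mean chain) and SI = T/C (the stability-ratio form, which
makes SSI·(1 − xT/xC) = 1 − SI an exact identity; a T/xT variant is
selectable). SSI requires xT ≠ xC. The composite STS is the plain sum of
the seven indices exactly as defined, even though it mixes a
susceptibility index into a tolerance sum and is dominated by the
mg-scale productivity terms; a z-score-standardized composite is emitted
alongside in cohort tables, clearly labeled as a non-standard companion.

## Classification

Technique 1 scores each trait against the fitted population mean ± SD:
efficient (> μ+SD) = 3 points, medium (closed interval [μ−SD, μ+SD]) = 2,
inefficient (< μ−SD) = 1; the default trait list is SDW, RDW, TDW, RSR,
PCONC, PUPE, PUTIE (max 21). Weights and trait list are configurable —
published scorecards of this kind sometimes quote other maxima (e.g. "out
of 20") without stating the per-trait scheme, so the scheme here is
explicit in the output metadata. Missing traits contribute 0 points and
are flagged. Totals are invariant to affine trait rescaling because the
cuts move with the scale.

Technique 2 cuts dry mass (efficiency axis) and PutiE (responsiveness
axis) at their population means; boundary equality counts as above, and
the quadrants map (x≥, y≥) → ER, (x≥, y<) → ENR, (x<, y≥) → IR,
(x<, y<) → INR. Axes are configurable since the convention varies across
the source literature. Technique 3 bins dry mass and P uptake at μ ± SD
into 3 × 3 groups (tercile cuts selectable). Technique 4 ranks by
descending STS. All ties break lexicographically by genotype id, making
every ranking deterministic. Top-fraction selection takes
k = floor(fraction × N); at N = 85 and 10% that is k = 8.

## Pipeline and outputs

`run_pipeline` sequences ingest/simulate → summaries → heritability →
efficiency → classification, writing each table twice (full precision for
machines, 2 decimals for reading) plus a checksummed manifest. Partial
failures degrade gracefully: a missing P-concentration channel skips the
uptake-dependent outputs and says so in the manifest; unbalanced data
skips the ANOVA stage likewise. With a fixed seed the whole bundle is
byte-for-byte reproducible.

## Known limitations

* Method-of-moments only; unbalanced or missing-cell designs are out of
  scope by construction.
* The truncation of negative components biases small σ²GE estimates
  upward in noise-dominated settings (a known property of ANOVA
  estimators).
* The normal + clamp-at-zero generative model cannot represent the
  right-skewed distributions of count-like root traits.
* Technique 2/3 class boundaries depend on the sampled population, so
  class labels are panel-relative, not absolute.
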