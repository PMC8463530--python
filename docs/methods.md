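# Methods

## Model and assumptions

`targetmr` estimates the on-target effect of perturbing a drug-target
protein by two-sample, cis-restricted Mendelian randomization.  Genetic
associations with an outcome are regressed through the origin on genetic
associations with the exposure (the protein concentration, or a downstream
biomarker standing in for protein activity).  Identification rests on:

1. the instruments associate with the exposure (enforced by the per-variant
   F filter);
2. exposure and outcome associations come from non-overlapping samples
   (two-sample design), so residual weak-instrument error attenuates the
   slope toward the null rather than toward the confounded association;
3. no pre-translational horizontal pleiotropy: restricting instruments to
   the cis region around the encoding gene makes "all variant effects pass
   through the protein" plausible, and residual violations are policed by
   leverage/outlier pruning and the heterogeneity Q.

Because cis variants are mutually correlated, ordinary IVW is invalid; the
slope is fit by generalized least squares with error covariance
Ω = diag(s_y) ρ diag(s_y), where ρ is the signed LD correlation estimated
from a reference dosage panel and oriented to the harmonized effect
alleles.  The multivariable model replaces the exposure vector with an
m × k matrix of mediator betas and apportions the total effect among
candidate mediators (e.g. LDL-C vs HDL-C); it additionally assumes all
relevant mediators are included.

Trial evidence is summarized per compound: per-trial effects (log odds
ratios from 2×2 tables, or between-group differences in percent change
from baseline) are pooled by inverse variance within compound, and a
Cochran Q across the pooled compound effects tests whether the compounds
share one effect.  Discordance between compounds — with the genetic
estimate as the on-target anchor — is the signature of compound rather
than target failure.  The comparison is visualized and clustered on
sign(effect) · (−log₁₀ p) evidence scores.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `maf_min` | 0.01 | minor-allele-frequency floor for instruments |
| `f_min` | 15 | per-variant F = (b_x/s_x)², squared Wald ratio; limits weak-instrument bias |
| `r2_max` | 0.40 | greedy-clump ceiling; ranked by exposure p, ties by position |
| `palindrome_eaf_limit` | 0.42 | A/T and C/G variants are kept only when both EAFs are outside (0.42, 0.58); strict drop mode available |
| `leverage_mult` | 3 | flag hat values above 3·k/m in the whitened design |
| `prune_alpha` | 0.05 | Bonferroni level for squared standardized residuals (χ²₁), α/m per variant |
| `overdispersion` | off | inflate se(θ̂) by √max(1, Q/df) |
| p floors | 1e−16 / 1e−60 | heatmap exports / clustering matrix respectively |
| linkage, metric | complete, Euclidean | clustering of the evidence matrix (unreported in the source analyses; recorded in the manifest) |

Pruning removes one worst offender per refit pass (outliers preferred over
leverage when both are flagged) and never goes below max(3, k+1)
instruments.  All thresholds are echoed into the run manifest.

## Standard errors and coverage

Ω uses outcome standard errors only — the first-order two-sample
convention.  Exposure-side uncertainty (s_x) is deliberately not
propagated; it enters only through the F filter.  The consequence,
measured on this package's own simulations, is a mild undercoverage of the
plain 95% CI (~92% at the default 1:5 exposure:outcome sample-size ratio),
because the residuals b_y − θ̂ b_x carry an extra θ²s_x² component that Ω
does not model.  The heterogeneity statistic absorbs exactly this
component, so the overdispersion option — se × √max(1, Q/df) — restores
near-nominal coverage (≈94% over 200 replicates at the default generator
conditions).  Calibration tests and the acceptance script therefore
exercise the overdispersion-robust interval; analyses that need strictly
model-based SEs can leave the flag off, accepting the first-order
approximation.

## What the generator emulates — and what it does not

`synthetic_data` draws standardized genotype scores from a multivariate
normal with AR(1) correlation (ρ = 0.5 by default, a realistic
within-block decay), builds the protein as a sparse linear genetic signal
(5 causal variants among m = 50) plus unit noise, optional mediators as
alpha·protein + own sparse cis effects + noise, and the outcome as
θ·protein (or Σβ·mediator) + noise, optionally thresholded to a binary
trait analyzed by per-variant logistic regression.  Summary statistics are
computed by marginal regressions in three disjoint samples (default
10,000 exposure / 50,000 outcome / 5,000 reference, the reference matching
the size of a typical external LD panel), so the two-sample guarantee
holds by construction.  Mediators receive small direct cis effects on
distinct variants; without them mediator beta profiles would be exactly
proportional and the multivariable model unidentifiable.

Continuous multivariate-normal dosage surrogates reproduce the covariance
structure that summary statistics inherit, which is all the estimators
consume; a discrete {0,1,2} mode (liability-threshold haplotypes) is
available but attenuates LD slightly.  The generator does **not** mimic
real regional LD (block boundaries, recombination hotspots), allele-
frequency–dependent effect sizes, sample overlap, population structure, or
phenotype covariates.  Passing tests therefore demonstrate correctness of
the estimators under their stated assumptions — not robustness to
structure the generator does not produce.

Trial simulation draws percent-change mean differences as
N(true MD, 2·sd²/arm) with the SE reported via a consistent 95% CI, and
binary events as binomials with compound-specific odds ratios applied to a
10% control risk; defaults emulate a four-compound inhibitor literature
(two potent compounds, one with an off-target harm, one weak) across 15
trials of 1,300 per arm.

## Numerical choices

- Variant identity is chrom:pos:unordered-allele-pair; rsIDs are carried,
  never matched on.  Coordinates 1-based, windows inclusive both ends; no
  liftover — build mismatch is an error.
- Correlation matrices are repaired to non-negative-definite by flooring
  eigenvalues at zero (tolerance 1e−8) with the repair magnitude logged;
  Ω is inverted by symmetric eigendecomposition and declared singular when
  the smallest eigenvalue falls below 1e−8 of the largest (the error
  advises a lower clump threshold).
- Clump ties at equal p are broken by smaller position, making the output
  invariant to input row order; r² exactly at the ceiling is retained.
- The 0.5 continuity correction is applied to all four cells of any
  zero-cell 2×2 table; double-zero trials are excluded and logged.
- 95% intervals use the normal quantile 1.959964 throughout.
- All randomness flows from one explicit seed through
  `numpy.random.default_rng` child streams; identical config + seed gives
  bit-identical outputs (checksummed in the manifest).

## Open design points resolved here

- Clumping is re-run per outcome on the harmonized intersection (coverage
  differs between outcome GWAS); ranking uses the exposure-weighting
  trait's p-value.
- Palindromic policy (EAF concordance at limit 0.42, strict-drop option)
  and position-based matching are package decisions; the source analyses
  do not state theirs.
- Random-effects flavor is DerSimonian–Laird; meta-regression is
  per-trial with method-of-moments τ² on the weighted residuals.
- The evidence-matrix clustering claims only the transform pipeline
  (signed log-p, square-root compression, agglomerative clustering), not
  any particular published leaf order, since metric and linkage are not
  reported for the original figures.

## Problem sizes used in checks

Calibration checks run at the default generator conditions (m = 50,
10k/50k/5k) over 200 replicates for recovery/coverage, 2,000 simulated
trial datasets for the between-compound type-I error, and 100 replicates
for multivariable null-mediator coverage; oracle comparisons (closed-form
IVW, exhaustive clumping, hand-computed pooling) run on 2–10-variant
instances at tolerance 1e−10.
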