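# Methods

## Scope and data model

`sigrisk` evaluates a given gene signature against a gene-expression matrix
with right-censored outcomes. It does not discover signatures and fits no
penalized models; the analysis is deliberately the classical one — a single
multivariate Cox proportional-hazards model over the signature genes, a
linear risk score, and group-based survival comparison.

Inputs are an `ExpressionMatrix` (probes/genes × samples, log2 scale after
preprocessing), a `ClinicalTable` (time > 0, event ∈ {0,1}, optional
covariates), a `GeneSignature` (identifiers, optionally all weighted), and
optionally an NCBI `gene_info`-format annotation file for identifier
resolution. Samples are joined by intersection of expression and clinical
ids, with dropped ids reported.

## Identifier resolution and probe collapsing

Lookup precedence is exact Entrez id, then official symbol
(case-insensitive), then Ensembl/HGNC cross-reference, then synonym; a
synonym naming several genes resolves to the record whose official symbol
sorts first and is flagged `synonym-ambiguous`. Genes measured by several
probes are collapsed by `max_row_average` (keep the probe with the largest
across-sample mean, values untouched — the default), `mean`, or
`max_variance`; ties keep the lexicographically smallest probe id so the
result is a pure function of the input.

## Preprocessing

`log2='auto'` transforms v ↦ log2(v + pseudocount) (pseudocount default 1)
only when the matrix maximum exceeds 50, a threshold that separates linear
intensities/counts from already-log2 data and makes the step idempotent.
Quantile normalization maps each sample onto the reference distribution
formed by averaging the sorted columns; tied values within a column receive
the mean of the reference quantiles they span, the standard microarray
dialect. Missing values are imputed by row mean before modeling (Cox
requires complete rows); a drop-samples policy is available.

## Survival estimators

All estimators are implemented directly on NumPy arrays:

- **Kaplan–Meier**: product-limit S(t) = Π_{tᵢ≤t} (1 − dᵢ/nᵢ) over distinct
  event times; right-continuous step evaluation.
- **Log-rank (k groups)**: (O−E)ᵀV⁻¹(O−E) over the first k−1 groups, with
  hypergeometric covariance summed over event times; df = k−1, p from the
  chi-square upper tail. All-censored input returns statistic 0, p = 1.
- **Cox**: Newton–Raphson on the partial likelihood, Efron (default) or
  Breslow ties; covariates centered for conditioning (β unchanged);
  log-sum-exp shift guards overflow; step-halving enforces monotone
  likelihood ascent. Convergence when max |gradient| < 1e-8 or relative
  log-likelihood change < 1e-9, at most 50 iterations; non-convergence
  (e.g. monotone likelihood) is flagged with a warning. Standard errors
  come from the inverse observed information; per-gene Wald p-values are
  two-sided normal.
- **Hazard ratio**: univariate Cox on the 2-level group indicator with a
  95% Wald interval; no events in one group yields an unbounded interval
  and a monotone-likelihood warning.
- **Concordance**: Harrell's C over comparable pairs — (i, j) comparable
  when tᵢ < tⱼ and subject i had the event; tied times are not comparable;
  tied scores count ½. This estimator choice is explicit because several
  variants exist.

## Risk groups

The quantile split orders samples by PI (stable sort) and cuts them into k
contiguous blocks whose sizes differ by at most one, with remainder samples
going to the lower-risk groups. Thresholds are midpoints between the
flanking PI values, so for k = 2 and even n the threshold is the median PI.

The optimized split scans every admissible boundary of the PI-ordered
samples, computing the two-group log-rank statistic for all candidates in
one vectorized pass (suffix sums over risk-set and death indicator
matrices), and picks the boundary with minimum p-value, earliest position
on ties. Admissibility requires each group to contain at least
`min_group_size` samples — default max(5, ⌈0.1·n⌉), because an
unconstrained scan can isolate near-empty groups with degenerate
statistics — and forbids splitting tied PI values (ties stay on the
lower-risk side, so labels remain a function of the PI). For k > 2,
boundaries are initialized at the quantile split and refined one at a time,
left to right, each by the same two-group scan restricted to the samples of
its two adjacent groups; iteration stops after a full cycle without a move
(each accepted move strictly lowers that boundary's scan p-value; a
100-cycle cap guards pathological cycling and is logged if hit).

The minimum-p split is a maximally selected statistic and its naive
p-value is reported as such (fidelity to common practice);
`split_pvalue_bias_check` permutes (time, event) jointly against the PI and
returns the add-one-smoothed fraction (1 + #{permuted min-p ≤ observed}) /
(1 + n_perm) — an honest selection-adjusted p-value, opt-in, requiring
n_perm ≥ 100.

## Time-dependent ROC

At horizon t, cases are subjects with an event by t and controls those
event-free past t (cumulative/dynamic definition). Censoring before t is
handled by either the Kaplan–Meier-conditional estimator (overall KM for
P(T>t), subset KM above each threshold; can be non-monotone, so the curve
is clipped to [0,1] and monotonized by cumulative envelopes) or the
nearest-neighbor estimator (per-subject weighted KM over marker-percentile
windows of half-width span, default 0.25·n^(−0.2); monotone by
construction and the default). AUC is the trapezoid area with (0,0) and
(1,1) appended; within equal false-positive rate the points are ordered by
increasing sensitivity, which makes the zero-censoring KM case reduce
exactly to the Mann–Whitney statistic with half-credit ties. The NNE
estimator smooths, so a perfect marker approaches but does not exactly hit
AUC = 1; the KM variant is exact there.

## Meta-base merging

Cohorts on a shared platform are merged by: per-cohort quantile
normalization (order of operations follows the recipe literally), then per
probeset a pure shift of each cohort's values to the unweighted grand mean
of the cohort means — unweighted so large cohorts do not dominate — which
preserves each cohort's standard deviation exactly, then concatenation
restricted to the probesets present in every cohort (a union would create
missingness the downstream model cannot represent). An audit table records
pre/post means and SDs per (probeset, cohort).

## Synthetic cohorts

The generator draws per-gene expression from Normal(μ_g, σ) on the log2
scale with μ_g ~ Uniform(6, 10) and σ = 1 (typical microarray ranges), and
event times from a proportional-hazards model with cumulative hazard
(λt)^shape · exp(PI), shape = 1 (exponential) by default, where the true
PI uses centered expression so λ (default 0.1 per year) is the rate of a
median subject. Censoring is an independent exponential (default rate
chosen for ~30% censoring under a null signature, the typical fraction in
the cohorts this tool targets) and/or an administrative cutoff. Defaults:
n = 200 samples, true β = (0.7, −0.5, 0.3, 0, 0) — two strong genes, one
moderate, two null — and 20 noise genes. The generator emulates none of
the probe-level artifacts of real arrays (probe effects, saturation,
platform-specific missingness), so passing tests demonstrate correctness
of the estimators and pipeline, not robustness to microarray noise.

The multi-cohort variant applies per-cohort location/scale distortions to
the expression (survival is linked to the undistorted values), giving the
merge step a known batch effect to remove.

## Problem sizes and numerical choices

The test suite exercises the estimators at n between 3 and 2000: oracle
equivalence (KM, log-rank, concordance, exhaustive split scan) on small
fixtures; coefficient recovery at n = 2000; calibration of the median
split over 2000 null replicates at n = 100 and of the permutation-adjusted
optimized split over 200 replicates with 100 permutations each — sizes
chosen so the chi-square asymptotics the tests assert actually apply while
the suite stays quick. Tolerances: oracle equalities at 1e-10–1e-12;
gradient-vs-finite-difference at 1e-6; grid-search maximizer agreement at
1e-4.

## Known limitations

- Localization of the optimized cutpoint is intrinsically noisy: with a
  hazard ratio of 3 across the true boundary (n = 300, no censoring) the
  exact-argmin estimator lands within ±2 ordered positions of the truth in
  only ~69% of replicates (~88% within ±5, measured over 200 seeds). This
  is a property of maximally selected log-rank statistics, not of the
  implementation, which is verified exactly against an exhaustive scan.
- No time-varying covariates, stratified-baseline Cox, frailty terms,
  penalized fits, or incident/dynamic ROC variants.
- Per-group concordance (reported when groups are analyzed separately) is
  computed within each group's samples; other readings of a "per-group"
  concordance exist.
- The Welch t-test is used for two-group per-gene comparisons (safer under
  unequal variances than the pooled test); the headline count of
  differential genes uses unadjusted p < 0.05, with Benjamini–Hochberg
  values reported alongside.
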