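# sigrisk

Survival analysis and risk assessment of multi-gene expression signatures.

Validating a proposed prognostic signature — a list of genes whose joint
expression is claimed to predict a censored clinical outcome such as death,
relapse or metastasis — requires the same pipeline every time: map the gene
list onto the expression platform, collapse multi-probe genes, fit a
multivariate Cox proportional-hazards model, reduce each patient to a
single risk score, split the cohort into risk groups, and quantify how well
the groups separate. `sigrisk` implements that pipeline as a library and a
command-line tool, for bioinformaticians and biostatisticians who want the
whole analysis scriptable and reproducible on their own matrices.

## The model

For sample *s* with expression values *x₁…x_p* on the signature genes, the
**prognostic index** is the linear predictor of the Cox model

PI(s) = β₁x₁(s) + β₂x₂(s) + … + β_p x_p(s),

where the coefficients β either come from one multivariate Cox fit of all
signature genes (partial-likelihood maximization by Newton–Raphson, Efron
or Breslow tie handling) or are supplied by the user as fixed weights.
Higher PI means higher modeled risk. Samples are stratified into k risk
groups either by

- **quantile split** — k contiguous, (near-)equal-sized blocks of the
  ordered PI; for k = 2 this is the median split; or
- **optimized split** — a log-rank test evaluated at every admissible
  cutpoint of the ordered PI, choosing the split with the minimum p-value
  (for k > 2, one boundary is refined at a time until no boundary moves).

The groups are then compared with the Kaplan–Meier estimator, the k-sample
log-rank test, the hazard ratio (univariate Cox on the group indicator),
Harrell's concordance index of the PI, per-gene Welch t / one-way F tests
across groups, and time-dependent ROC curves (cumulative cases vs. dynamic
controls, Kaplan–Meier-conditional or nearest-neighbor estimator).

Because the minimum-p cutpoint is a maximally selected statistic, its naive
p-value is optimistic; `split_pvalue_bias_check` provides a
permutation-based selection-adjusted p-value.

A separate `metabase` module merges cohorts measured on a common platform:
per-cohort quantile normalization, per-probeset equalization of cohort
means to their grand mean with each cohort's standard deviation preserved,
and concatenation over the shared probesets.

## Worked example

```
sigrisk simulate --n 120 --seed 5 --noise-genes 5 --outdir fx
sigrisk run --expression fx/expression.tsv --clinical fx/clinical.tsv \
            --signature fx/signature.txt --outdir out --k 2
```

which prints (one JSON line; numbers from this exact invocation):

```
{"outdir": "out", "logrank_p": 3.1144874243789074e-09, "c_index": 0.7829069336}
```

The simulated cohort has 120 samples and a 5-gene signature with true
coefficients (0.7, −0.5, 0.3, 0, 0) plus 5 noise genes. The median split
of the Cox prognostic index separates the two 60-sample risk groups with a
log-rank p ≈ 3×10⁻⁹, and the PI ranks patients by observed event order
with concordance ≈ 0.78 — the signature is (by construction) strongly
prognostic. `out/` contains the Kaplan–Meier figure and its plotted
numbers (`km.png`/`km.tsv`), the risk-ordered heat map, per-gene box plots
with test p-values, the PI-vs-group panel, the coefficient table
(β, SE, Wald p per gene), and `summary.json` with every statistic.

Other subcommands: `sigrisk merge` (meta-base construction from ≥ 2
expression TSVs) and `sigrisk roc` (time-dependent ROC of a stored PI).

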