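# Methods

This note documents the statistical procedures, the defaults and why
they were chosen, the synthetic-data model used for validation, and the
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Differential expression

Each gene is tested tumor-vs-normal on the values as supplied (linear
or declared log2 scale; the scale is never inferred, because a silent
misdetection would corrupt every fold change).

**Normality gate.** The Anderson–Darling statistic
A² = −n − (1/n)·Σ (2i−1)[ln Φ(wᵢ) + ln(1−Φ(w_{n+1−i}))] is computed on
standardized sorted values, corrected to A\* = A²(1 + 0.75/n + 2.25/n²),
with the p-value from the D'Agostino–Stephens piecewise-exponential
approximation for estimated parameters (the same approximation used by
the reference normality-test implementations in R and statsmodels; we
call statsmodels and apply the small-sample correction to the reported
statistic). The parametric branch requires normality acceptance
(p > 0.05) in *both* classes and ≥ 8 samples per class; any failure —
including zero variance or small n — routes the gene to the rank test.
This both-classes rule is deliberately conservative: the nonparametric
branch is always valid, just less powerful.

**Tests.** The two-sample z-test uses unpooled plug-in sample variances,
z = (x̄_t − x̄_n)/√(s_t²/n_t + s_n²/n_n). The Mann–Whitney U test uses
the exact null distribution when n_t + n_n ≤ 16 and the data are
tie-free, otherwise the tie-corrected normal approximation with
continuity correction.

**Fold change.** On the linear scale, log2FC = log2((x̄_t+ε)/(x̄_n+ε))
with a pseudo-count ε = 0.25 (configurable) to avoid infinite ratios at
zero means; on the log2 scale it is the difference of means.

**Selection and ranking.** Benjamini–Hochberg adjustment runs across
all tested genes; genes pass with adjusted p < 0.05 and |log2FC| ≥ 1.5.
The retained list is ranked by adjusted p (ties: larger |log2FC|, then
gene id) and truncated to the input size *n* over both directions
combined; ranking by adjusted p keeps the cut consistent with the
significance criterion, and a per-direction mode is left to callers who
want balanced up/down lists. Note that BH re-adjustment is not an
identity operation: applying the step-up formula to already-adjusted
values can only increase them (e.g. [0.25, 1.0] → [0.5, 1.0] →
[1.0, 1.0]), so adjusted p-values must be computed once, from raw
p-values.

## Disease-term over-representation

The query (DEG list) is tested against every term with the one-sided
hypergeometric upper tail P(X ≥ k), k the overlap inside the universe.
The universe defaults to the intersection of the expression dataset's
genes with all annotated genes — the defensible background when the
assay, not the annotation release, defines which genes could have been
called — and can be switched to "all annotated genes". Terms with
fewer than 2 universe genes are skipped so degenerate tests do not
inflate the BH correction count. Ancestor propagation along `is_a`
edges (each term inheriting its descendants' genes) is available but
off by default, matching the common practice of consuming a pre-built
annotation release directly. DEGs are retained iff they belong to ≥ 1
term with adjusted p < 0.05, preserving their original order.

## Wilks' lambda stepwise selection

For a candidate set S, Λ(S) = det(W)/det(W+B) with W the pooled
within-class and B the between-class cross-product matrices, computed
via log-determinants for stability; a non-positive determinant signals
a singular within-class scatter and the offending candidate is skipped
(logged) rather than aborting the run. Entry of the (p)-th feature is
tested by the partial F statistic
F = ((1−Λ_partial)/Λ_partial)·(N−g−p+1)/(g−1), Λ_partial the ratio of
consecutive overall lambdas, on (g−1, N−g−p+1) degrees of freedom.
Selection is greedy forward (no backward step): the candidate
minimizing Λ enters while its entry p ≤ the current niveau; ties at
equal Λ imply equal partial F and break lexicographically on gene id,
making reruns deterministic. Selection stops when the error degrees of
freedom would be exhausted.

The trimming loop starts at niveau 0.10 and, whenever any entered
feature has entry p > 0.05, lowers the niveau by 0.01 and reselects,
down to a floor of 0.05 — an arithmetic schedule bounded at six
iterations, chosen for transparency; both the schedule and a
"filter-only" variant (truncate the first-pass trace instead of
reselecting) are exposed as options. The loop returns the last
non-empty selection.

A property of forward stepwise selection worth stating plainly: when
many null candidates compete, the minimum of their conditional entry
p-values is small with high probability (≈ 1 − 0.95^m at threshold
0.05 with m candidates), so a handful of false entries after the true
features is expected, and strongly correlated true features are partly
redundant once a few have entered. The pipeline mitigates this by
placing the enrichment filter before selection, which shrinks the
candidate pool to mostly signal-bearing genes.

## Classification gate

Samples are split per class with train size round(0.8·class size),
using a seeded permutation. Features are standardized with train-set
mean/SD inside the model pipeline — RBF kernels on raw FPKM scales are
otherwise dominated by high-expression genes. The (γ, C) grid is
log10-spaced, one point per decade over [1e−6, 1e6] and [1e−5, 1e5];
mean stratified 10-fold CV accuracy picks the winner, ties resolving
toward smaller C then smaller γ (weaker regularization pressure and
smoother boundaries preferred when indistinguishable). The held-out
report recomputes accuracy, sensitivity, specificity and Cohen's kappa
from raw confusion counts (tumor positive); the accuracy-vs-NIR test is
the exact one-sided binomial upper tail, not a normal approximation.
ROC scores are signed distances to the decision boundary; AUC uses the
rank formulation with midranks, so any strictly monotone rescoring
leaves it unchanged. The PCA check reports the variance fraction of the
top components (default 2) of the signature matrix and gates at 80%.

## Prognostic screen

Per gene, samples with survival records are median-split (ties at the
median to "low"); low/high groups are compared by the log-rank test
with variance term d·(n_A/N)(1−n_A/N)(N−d)/(N−1) per distinct event
time, events preceding censorings at tied times. The hazard ratio is
the Pike O/E estimator (O_high/E_high)/(O_low/E_low) — self-contained
and iteration-free; a Cox model is deliberately out of scope. Genes
whose split leaves fewer than two samples on a side, or with zero
variance, are skipped with a log message. A zero log-rank variance is
reported as a degenerate comparison with p = 1 rather than an error.

## Synthetic data model

`FixtureSpec` defaults describe the validation conditions: 1000 genes,
30 tumor + 30 normal samples, per-gene baselines drawn once from
N(5, 1.5) on the log2 scale, within-class noise SD 0.5 log2 units,
15 planted genes shifted ±2 log2 units in tumor samples (random sign
per gene), exponentiated to a linear FPKM-like scale. One disease term
covers 80% of the planted genes plus background genes at rate 0.05;
19 further terms draw random gene sets of size 10–40. Survival is
generated for tumor samples with exponential times, baseline rate
ln2/730 per day (median ≈ 2 years), log-hazard linear in one designated
planted gene's log2 expression with slope 1.25 — about a two-fold rate
ratio across that gene's median split — and independent exponential
censoring calibrated to ≈ 30% censored. All randomness flows from a
single integer seed through `numpy.random.default_rng`, so fixtures are
bit-identical across runs and platforms.

What the generator does *not* emulate: batch effects, platform
differences, count-level sequencing noise, gene–gene correlation
structure, or informative censoring. Passing tests therefore
demonstrate correctness of the machinery and calibration under the
stated model, not robustness to real-data artifacts.

Problem sizes used by the validation suite were chosen to exercise the
statistics at meaningful scale while staying desk-sized: 1500-gene null
matrices for calibration, 20 pipeline seeds for planted recovery, 50
seeds × 200 samples for prognostic power.

## Numerical and I/O choices

- Overall lambdas are floored at 1e−300 and clipped to [floor, 1];
  partial lambdas are clipped to ≤ 1 before the F transform so rounding
  can never produce a negative F.
- Expression and survival writers use `%.17g`, which round-trips every
  IEEE double exactly; readers parse through `astype(float)` (correctly
  rounded) after locating non-numeric cells, because pandas'
  `to_numeric` fast path is not correctly rounded.
- Duplicate gene rows collapse to the row with the highest mean — a
  deterministic rule borrowed from probe-collapse practice; the count
  of collapsed rows is logged.
- A single pipeline seed spawns per-stage seeds (split, CV folds)
  through `numpy.random.SeedSequence`, and the result JSON contains no
  timings, so identical config + seed reproduces byte-identical
  reports; wall-clock timings live in `provenance.json`.

## Known limitations

- Two-class problems only; no multi-class discriminant support.
- No count-model (negative-binomial/Wald) branch: inputs are assumed
  normalized, and raw counts should be normalized upstream.
- No class-imbalance correction beyond stratified splitting and CV.
- Stepwise selection inherits the false-entry behavior described above;
  signature sizes, not identities, should be trusted near the entry
  threshold.
- The prognostic screen is univariable; hazard ratios from the Pike
  estimator are slightly conservative relative to Cox estimates when
  hazards are strongly non-proportional.
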