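# Methods

## Scope and data model

`txrestore` analyzes a normalized log2 expression matrix (genes × samples)
with a study design naming one healthy baseline group, one disease group and
any number of treatment groups, each with at least two replicates. Values
are assumed already normalized on the log2 scale; the loaders never
transform values, never impute (missing cells are a hard error), and treat
gene identifiers as opaque strings — probe-to-gene collapsing, normalization
and annotation curation are upstream of this package. Gene-set annotations
arrive as standard GMT.

## Differential expression

For a contrast of group A against group B, logFC_g = mean_A(g) − mean_B(g);
the control group always goes second, so all pipeline contrasts are
"condition vs WT" or "treatment vs disease".

Two statistics are available:

* **ordinary** — pooled-variance two-sample t with d = n_A + n_B − 2 df.
* **moderated** (default) — empirical-Bayes variance shrinkage. Writing
  s²_g for the pooled variance, the model takes s²_g | σ²_g as scaled
  chi-square with d df and σ²_g as scaled inverse chi-square with prior df
  d₀ and scale s₀². Then log s²_g has known mean/variance offsets
  (digamma/trigamma terms), so (d₀, s₀²) are estimated by matching the first
  two moments of log s²_g across genes, inverting the trigamma function with
  Newton's method. The posterior variance is
  s̃²_g = (d₀·s₀² + d·s²_g)/(d₀ + d) and the moderated statistic
  t̃_g = logFC_g / (s̃_g·√(1/n_A + 1/n_B)) is referred to t with d₀ + d df.
  When the spread of log variances does not exceed what chi-square sampling
  alone explains, d₀ = ∞ and every gene uses the common prior variance.
  This estimator agrees with the standard R reference implementation of the
  moderated t to ~1e−13 on a fixed heteroscedastic fixture (frozen in the
  test suite).

With three replicates per group — the regime this package targets — the
ordinary t's variance estimate on 4 df is unstable, which is why moderation
is the default; the ordinary mode is kept for calibration checks and large-n
work.

Degenerate genes: zero pooled variance with zero logFC yields t = 0, p = 1
in ordinary mode; zero variance with nonzero logFC falls back to the
moderated statistic (a warning reports the count). P-values are clipped into
(0, 1] so downstream filters stay well defined.

Multiple testing uses Benjamini–Hochberg step-up FDR, applied **per
contrast** (not pooled across contrasts). BH is delegated to statsmodels and
cross-checked in the tests against a brute-force evaluation of the step-up
definition.

## Signature selection

A gene enters a contrast's signature when |logFC| ≥ 1 and adjusted
p ≤ 0.05, both boundaries inclusive; both thresholds are parameters and are
recorded on the resulting signature object. The disease signature uses the
disease-vs-WT contrast; the extended altered set is the union of the
selections from the disease and every treatment-vs-WT contrast, capturing
genes a treatment perturbs that the disease does not. Which contrasts enter
the union is an explicit argument, since either convention (treatments vs
WT only, or also treatments vs disease) is defensible; the pipeline default
is the vs-WT family. Overlaps between per-contrast signatures are reported
as exclusive-combination counts (the cells of an upset plot), which by
construction sum to the union size.

## Clustering and distance from healthy

Signature genes are described by their vector of logFC-vs-WT values across
all conditions and clustered with Ward agglomerative clustering, which
minimizes the increase in within-cluster sum of squares at each merge and
therefore presumes the squared-Euclidean geometry these vectors live in.
Heights follow the convention in which each merge height is the square root
of the merged criterion; the flat partition at a fixed k — the only thing
used downstream — is convention-independent. The implementation delegates
to scipy's nearest-neighbor-chain Ward linkage; exact merge ties are broken
by scipy's deterministic internal ordering, which has measure zero on the
continuous profiles being clustered and never affects reproducibility for a
fixed input. The test suite verifies the partition against a from-scratch
greedy agglomeration that recomputes the Ward criterion at every step on
hundreds of small random instances. Cluster labels are canonicalized
1..k by decreasing size (ties by smallest member index), so partitions are
invariant to row order. k is a parameter, default 6 for gene profiles and 3
for category score vectors; no data-driven k selection is attempted. Rows
are clustered as raw logFC by default; an optional flag z-scores each gene's
row first (grouping by response shape rather than magnitude) — both
conventions are common and the choice is left explicit.

Distance from healthy is the mean of |logFC vs WT| over a gene group, per
condition — reported for all signature genes and for each cluster. The
overall value is exactly the size-weighted mean of the cluster values.

## Efficiency scores

For category C and treatment T, with N = mean over C of
|logFC_{T vs disease}| and D = mean over C of |logFC_{T vs WT}|:

    score(C, T) = log10( max(N, ε) / max(D, ε) ),  ε = 0.01 log2 units

Design choices, each genuinely open and resolved as follows:

* **Absolute values.** "Mean logFC" is the mean of absolute logFCs
  (displacement magnitudes). Signed means cancel between up- and
  down-regulated genes within a category, which would make the score's
  intended reading — restoration without disruption of the healthy state —
  unattainable; the distance analysis already uses the absolute-value
  convention.
* **Floor ε.** The raw ratio is undefined when a treatment exactly equals a
  baseline on a category. Flooring both means at ε = 0.01 bounds scores and
  keeps them deterministic; per-row flags record when the floor fired so a
  capped score is never mistaken for a measured one.
* **Direct vs-disease contrasts.** The numerator uses a directly computed
  treatment-vs-disease contrast rather than the difference of two vs-WT
  logFCs: identical in expectation, but with the correct replicate variance.
* **Shared universe.** Categories are intersected with one shared gene
  universe — the extended altered set by default — before scoring; sets with
  fewer than 5 surviving members are dropped, since a mean over fewer genes
  is dominated by single-gene noise.

Categories whose best score across treatments exceeds 1 pass the filter;
passing categories are Ward-clustered on their score vectors (default
k = 3). The score obeys two exact identities used as tests: multiplying all
vs-disease logFCs by 10 raises every unfloored score by exactly 1, and
swapping the two contrast sets negates every unfloored score.

## Synthetic data generator

The generator emulates the structure of a small microarray treatment study:
gene baselines b_g ~ N(7, 2²) log2 units; a fraction (default 5%) of genes
disease-perturbed by δ_g with |δ_g| ~ U(1, 3) and sign up with probability
0.5; each treatment restores an all-or-none Bernoulli(r) subset of disease
genes and perturbs a small fraction (default 2%) of non-disease genes by
±1.5 (off-target effects, mimicking treatment-specific gene deregulation
outside the disease signature); replicate noise is N(0, 0.25²) per
observation, homoscedastic by default with an optional scaled-inverse-
chi-square per-gene variance (`heteroscedastic_df`) to exercise variance
moderation. Defaults: 3 replicates per group, 3 treatment arms with
restoration fractions (0.4, 0.6, 0.9) representing a weak monotherapy, a
strong monotherapy and a near-complete combination.

All-or-none restoration (rather than partial shrinkage of δ_g) keeps the
ground truth crisp for cluster-level checks; a partial-restoration model
would blur the expected distances without changing any algorithm under
test. One integer seed drives a single pseudorandom stream with a fixed
draw order (baselines, disease assignment, effects, per-treatment draws in
treatment order, then noise), so outputs are byte-reproducible across runs
and platforms.

What the generator does **not** emulate: probe-level structure, batch and
hybridization effects, intensity-dependent variance, correlated gene
modules, or count-based (RNA-seq) sampling. Passing the synthetic
benchmarks therefore demonstrates the correctness and calibration of the
computations — not that any particular biological dataset satisfies the
model's assumptions.

## Verification strategy and problem sizes

* Closed-form and hand-enumerable cases (pooled t on one gene, BH on four
  p-values, efficiency scores 2.0 / −2.0 / log₁₀5) are asserted exactly.
* Ward clustering, BH adjustment and overlap counts are compared with
  independent brute-force implementations on hundreds of random instances
  (Ward at n ≤ 15, where exhaustive recomputation of the criterion is
  cheap).
* The moderated t is validated against frozen values from the standard R
  reference implementation on a 60-gene heteroscedastic fixture.
* Statistical checks run at deliberately modest sizes chosen to keep the
  suite fast while leaving comfortable statistical margins: type-I error on
  20 null datasets of 10,000 genes (3 vs 3); signature recovery on 10
  datasets of 2,000 genes at noise sd 0.25 and effects ≥ 1.5 (expected
  per-gene miss probability < 1%); restoration monotonicity on 20 datasets
  of 800 genes with restoration fractions 0, 0.5, 1.
* Two published headline counts from the study whose deposited DE tables
  motivated the artifact's file formats (an 867-gene disease signature and
  a 3733-gene extended set) can be recomputed by the suite when that
  deposited table is placed at `data/published_de_vs_wt.tsv`; the table is
  not redistributed with the package, so those two checks report as
  failures in its absence rather than silently passing.

## Known limitations

* The moderated t assumes approximately Gaussian log-intensities and
  exchangeable variances across genes; strong mean-variance trends would
  call for an intensity-dependent prior, which is not implemented.
* Multi-factor designs, batch covariates and paired samples are out of
  scope (single-factor group comparison only).
* Efficiency scores are means over category members; overlapping categories
  are scored independently with no redundancy reduction, and no enrichment
  p-value accompanies the score.
* BH is applied per contrast; global adjustment across all contrasts would
  be more conservative for the extended-set union.
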