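# txrestore

Quantifying how well drug treatments restore a diseased transcriptome to the
healthy state.

## The problem

In preclinical models of chronic inflammatory disease — the motivating case
is TNF-driven arthritis in transgenic mice, profiled by expression arrays of
whole joint tissue with a handful of replicates per group — a treatment's
molecular efficacy can be read from how far the treated transcriptome still
sits from healthy wild-type (WT) controls, and how completely it has left
the disease state. `txrestore` implements that analysis as a reusable,
tested pipeline for anyone comparing one healthy baseline group, one disease
group and any number of treatment arms on a normalized log2 expression
matrix.

## The method

Given log2 expression values for groups WT (healthy), TG (disease) and
treatments T₁…Tₖ (n ≥ 2 replicates each, typically n = 3):

1. **Differential expression.** For each condition X, per-gene
   logFC = mean(X) − mean(baseline) with either an ordinary pooled-variance
   two-sample t, or (default) an empirical-Bayes **moderated t**: per-gene
   variances s²_g are shrunk toward a prior s₀² with weight d₀ estimated by
   matching the first two moments of log s²_g across genes (trigamma
   inversion), giving t̃_g = logFC_g / (s̃_g·√(1/n_a + 1/n_b)) with
   d₀ + d_g degrees of freedom. P-values are two-sided;
   Benjamini–Hochberg step-up gives the FDR-adjusted p.
2. **Disease signature.** Genes with |logFC| ≥ 1 and adjusted p ≤ 0.05
   (inclusive boundaries) in the disease-vs-WT contrast. The **extended
   altered set** is the union of such selections over the disease and every
   treatment-vs-WT contrast.
3. **Restoration profiles.** Signature genes are clustered by Ward
   agglomerative clustering (squared-Euclidean geometry, default k = 6) on
   their logFC-vs-WT vectors across all conditions; for each condition the
   **distance from healthy** is the mean |logFC vs WT|, reported overall and
   per cluster. Zero means indistinguishable from healthy.
4. **Treatment efficiency per functional category.** For a gene-set category
   C (GO/KEGG/TF-target sets supplied as GMT) and treatment T,

   score(C, T) = log₁₀( mean_{g∈C} |logFC_{T vs disease}(g)| / mean_{g∈C} |logFC_{T vs WT}(g)| )

   with both means floored at ε = 0.01. A high score means the treatment
   moved C's genes far from the disease state while leaving them near the
   healthy state. Categories whose best score exceeds 1 (a tenfold ratio)
   pass the filter and are Ward-clustered (default k = 3) by their score
   vectors.

A seeded synthetic-data generator with known ground truth (which genes are
disease-perturbed, which each treatment restores) makes every stage testable
end to end without any external download.

## Worked example

```python
import txrestore as tx

config = tx.SimulationConfig(
    n_genes=1000, n_treatments=3,
    restoration_fractions=[0.3, 0.6, 0.95],
    treatment_names=["DRUG_A", "DRUG_B", "COMBO"],
    frac_disease_genes=0.1, effect_size_low=1.5, seed=42,
)
expr, design, truth = tx.simulate_expression(config)
sets = tx.simulate_gene_sets(truth, n_sets=40, disease_enrichment=12.0, seed=43)

model = tx.TreatmentRestorationModel(expr, design, gene_sets=sets)
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Treatment restoration analysis
==============================
genes: 1000   samples: 15
baseline: WT   disease: TG   treatments: DRUG_A, DRUG_B, COMBO
signature thresholds: |logFC| >= 1.0, adj_p <= 0.05
disease signature: 100 genes
extended altered set: 152 genes

mean |logFC| distance from healthy (rows: all + clusters)
            TG_vs_WT  DRUG_A_vs_WT  DRUG_B_vs_WT  COMBO_vs_WT
gene_group
all            2.361         1.653         1.199        0.259
1              2.318         1.607         0.163        0.270
...

functional categories scored: 39; passing score > 1.0: 19
efficiency scores of passing categories
treatment  DRUG_A  DRUG_B  COMBO
category
SET0001    -0.237  -0.003  1.209
...
```

Reading the output: the disease sits 2.36 log2 units from healthy on
average over the 100 signature genes; the three treatments (restoring 30%,
60% and 95% of disease genes in this simulation) land at 1.65, 1.20 and
0.26 — the strongest treatment is nearly back to the healthy state. The
per-cluster rows show *which* gene groups each drug restores (e.g. DRUG_A
fixes clusters 5–6, DRUG_B clusters 1 and 3, COMBO all of them), and the
efficiency table shows that only COMBO clears the score > 1 bar — it pulls
category genes off the disease state (numerator large) without displacing
them from healthy (denominator small).

The same analysis runs from the shell on TSV/GMT files:

```bash
txrestore simulate --config sim.yaml --out-dir data/
txrestore run --config pipeline.yaml       # de tables, signature, clusters,
                                           # distances, efficiency, manifest
```

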