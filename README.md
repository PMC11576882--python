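# iromics

Integrative transcriptome–proteome analysis of insulin-resistant kidney cell
models, re-built as a tested, fully synthetic-data-driven Python pipeline.

## The scientific problem

Diabetic kidney disease (DKD) is driven in part by cellular insulin
resistance in the glomerulus and proximal tubule. A common study design
profiles paired RNA (counts) and protein (TMT-style intensities) from
several kidney cell types — podocytes (Pod), glomerular endothelial cells
(GEC), mesangial cells (MC) and proximal tubular cells (PTC) — under basal
and insulin-resistant conditions, then asks which genes and pathways respond
consistently across cell types and whether those changes replicate in human
biopsy cohorts. This package implements that analysis chain for anyone who
wants to run it, test it, or benchmark it on data with known ground truth:

1. **Preprocessing** — cpm > 1 filter, TMM (trimmed mean of M-values)
   normalisation and log2-cpm transform for RNA; log2 + per-sample median
   centring for protein; autoscaling; PCA sample overview.
2. **Differential expression** — per-cell-type moderated-t contrasts
   (insulin-resistant − basal) with empirical-Bayes variance shrinkage
   `s²_post = (d₀s₀² + d s²)/(d₀ + d)`, Benjamini–Hochberg correction pooled
   globally across the four cell types, transcript–protein log2FC
   correlation, and cell-line-specific calling (significant in one cell
   type, p > 0.05 and |log2FC| < 0.1 in the others).
3. **Consensus OPLS-DA** — two-block data fusion: linear kernels
   K_b = X_bX_bᵀ (double-centred, unit Frobenius norm) weighted by the
   modified RV coefficient against the response kernel yyᵀ; one predictive
   plus one orthogonal latent variable; R², 7-fold cross-validated Q²,
   1000-permutation significance with a t-test against the null Q²
   distribution; VIP (root-mean-square 1 across the concatenated blocks).
4. **Consensus feature selection** — "Top-40"-style rule: VIP > 1 and
   FDR < 0.1 in ≥ 3 cell types with a consistent direction; hierarchical
   clustering of the selected log2FC matrix.
5. **Enrichment** — preranked GSEA (weighted Kolmogorov–Smirnov ES,
   gene-label permutations, NES, leading edge) under two rankings
   (signal2noise and consensus-model loadings), hypergeometric
   over-representation, and Wang graph-based semantic-similarity clustering
   of terms that are significant in both omics layers of at least one cell
   type.
6. **Biopsy validation** — average-Z pathway scores compared across donor /
   early-DKD / advanced-DKD groups by one-way ANOVA, SAM (significance
   analysis of microarrays) with permutation FDR, and Spearman phenotype
   correlation (GFR, ACR, slope).

A first-class synthetic-data module (`iromics.sim`) generates the whole
study — paired negative-binomial RNA counts and log-normal protein
intensities with planted shared and cell-type-specific effects whose
cross-layer correlation is controlled, a toy ontology with propagated
gene-set annotations, and a biopsy cohort with planted pathway gradients and
phenotype links — together with the ground truth needed to score recovery.

## Worked example

```bash
iromics run-all --outdir results/demo --seed 1
```

or step by step through the numbered drivers:

```bash
cd analysis
python 01_simulate.py && python 02_preprocess_pca.py && python 03_differential_expression.py
python 04_consensus_opls.py && python 05_select_features.py
python 06_enrichment.py && python 07_biopsy_validation.py
```

Output of a run at seed 1 (abridged):

```
rna: DE features at FDR<0.05 per cell type:
  GEC=42, MC=38, PTC=40, Pod=42
Pod: R2Y=1.000 Q2=0.256 perm_p=0.005 (t-test p=3.5e-124) lambda rna/protein = 0.45/0.55
selected 36 consistently regulated features
recovery vs planted shared genes: sensitivity=0.90, false-discovery proportion=0.00
retained 13 terms (p<0.05 and q<0.1 in both layers of >=1 cell type), in 4 similarity clusters
planted sets recovered among retained: ['T0027', 'T0028', 'T0029'] of ['T0027', 'T0028', 'T0029']
one-way ANOVA: F=19.6, p=3.30e-07
```

Reading this: ~40 RNA features reach FDR < 0.05 per cell type (40 shared +
30 cell-type-specific effects were planted); every cell type's consensus
model is far more predictive than its permutation null (perm_p = 1/(199+1),
the add-one minimum); the consensus selection recovers 90% of the planted
shared genes with no false selections; all three planted gene sets are
recovered by the enrichment filter; and the planted pathway gradient in the
biopsy cohort is highly significant by ANOVA. In-sample R²Y ≈ 1 is expected
for n = 10 samples against thousands of features — Q² and the permutation
test carry the evidence.

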