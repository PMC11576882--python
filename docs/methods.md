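# Methods

This note documents the models, numerical choices and known limits of the
`iromics` pipeline in the order the stages run.

## Synthetic study generator

The generator (`iromics.sim`) emulates a paired-omics insulin-resistance
study: `n_cell_types` (default 4) cell lines × 2 conditions (basal,
insulin-resistant) × `n_replicates` (default 5) replicates, with
`n_genes = 2000` features measured on both layers.

**RNA.** Gene baselines are log-normal (σ = 1.5 natural-log units) shared
across cell types, with a per-cell-type log2 jitter (sd 0.4) that makes
samples cluster by cell type, as bulk omics of distinct cell lines does.
Counts are gamma–Poisson (negative binomial) around library-size-scaled
expected fractions; library sizes are uniform on 0.5–2 ×10⁶. Gene-wise
dispersions are log-normal around `rna_dispersion = 0.05` (biological
coefficient of variation ≈ 0.22), a realistic figure for immortalised cell
lines run as technical-grade replicates.

**Protein.** log2 intensities are normal around a gene baseline
(N(20, 2)) plus a per-cell-type jitter (sd 0.5), with noise sd
`protein_cv = 0.2` log2 units, in line with isobaric-label quantification
precision.

**Planted effects.** `n_shared_signal = 40` genes are regulated in every
cell type and `n_specific_signal = 30` per cell type in one only. For each
planted gene, the (RNA, protein) effect pair is a shared random sign times a
bivariate normal centred at `effect_log2fc = 1.0` with spread
`effect_log2fc_sd = 0.75`. The jitter correlation is solved in closed form
so the expected Pearson correlation of planted RNA vs protein effects equals
`rna_protein_effect_corr = 0.5`; an infeasible solution (e.g. a near-zero
target with a tight spread) is clipped to ±1. The 0.4–0.6 target range
mirrors the transcript–protein regulation coupling reported for this class
of experiment. Batch is an optional additive log2 offset on the second
replicate partition (default 0); the differential model can block on it.

**Ontology and gene sets.** A rooted DAG is grown term by term (each new
term gets one `is_a` parent and, with probability 0.2, a second `is_a` or
`part_of` parent); direct annotations are Poisson-sized random gene sets and
propagate to all ancestors (true-path rule). When planting, the last few
terms are annotated predominantly with the upward-consistent shared genes,
making them genuinely enriched everywhere those genes respond.

**Biopsy cohort.** Three groups (living donors, early DKD, advanced DKD;
default 20 samples each) of log-scale expression; the upward-consistent
shared genes are shifted by 0, 0.5 and 1.0 × `shift_log2`. Phenotypes (GFR,
ACR, slope) are Gaussian-copula-linked to the first shifted gene with
configurable correlations (defaults −0.6, +0.5, −0.4); age is independent.

**What the generator does not model:** correlated noise across genes
(co-expression modules, latent technical factors), compositional coupling
between planted effects and library size, protein missingness, and
batch-by-condition confounding. Passing recovery tests therefore
demonstrate correctness of the machinery under clean noise, not performance
on real data — see "Known limits" for where this matters.

## Preprocessing

RNA features are kept when cpm > 1 (strictly) in at least one library;
filtering precedes normalisation. TMM factors follow the published defaults:
reference = sample whose upper-quartile cpm is closest to the mean upper
quartile; 30% two-sided trim on M-values, 5% on A-values;
inverse-asymptotic-variance weighting; factors re-centred to geometric mean
1. The log2-cpm transform is `log2((count + 0.5)/(lib·factor + 1) · 1e6)`.
The mean–variance precision weights of the full voom regression are
deliberately not propagated into the linear model; the moderated-t below is
the portable core. Consequence: p-values on count data are mildly
conservative (measured pooled null rate 0.0493 at nominal 0.05 over 50
seeded null studies; exactly-normal data measures 0.0499).

Protein intensities are log2-transformed and median-centred per sample
(grand median preserved); TMM's count model does not apply to intensities,
so median centring plays the equivalent role before the shared downstream
path. Autoscaling is per feature (mean 0, sd 1, ddof = 1) per cell type;
zero-variance features are dropped with a log entry.

## Moderated differential expression

Per cell type and layer, a least-squares fit of condition (plus optional
batch blocking) gives per-feature log2FC and residual variance s² on d
degrees of freedom. The prior (d₀, s₀²) is estimated by method-of-moments on
log sample variances (digamma/trigamma moments; trigamma inverted by Newton
iteration), then `s²_post = (d₀s₀² + d·s²)/(d₀+d)` and
`t = log2FC / (s_post√v)` on d₀+d degrees of freedom. `prior_df` can be
forced to 0 (ordinary t) or ∞ (full shrinkage) — both limits are tested.
BH correction is applied to the p-values pooled across the four cell types,
separately per layer; cross-layer pooling is not done. Cell-line-specific
calls require FDR < 0.1 in the focal cell type and, in every other cell type
where the feature was measured, p > 0.05 and log2FC strictly inside the
±0.1 band; features filtered out elsewhere (cell-line-restricted
expression) satisfy the other-cell-type constraint vacuously.

## Consensus OPLS-DA

Each autoscaled block gives a linear kernel K_b = X_bX_bᵀ, double-centred
and scaled to unit Frobenius norm. Block weights are
λ_b ∝ max(RV_mod(K_b, yyᵀ), 0), normalised to Σλ = 1, where RV_mod is the
modified RV coefficient (diagonals zeroed before the trace inner products).
The consensus kernel Σλ_bK_b is exactly the Gram matrix of the
block-scaled concatenated data, so the model is fitted in that feature
space: the predictive weight is w ∝ X̃ᵀy; each orthogonal component removes
the response-orthogonal part of the loading vector and deflates X̃ before
the final predictive fit. This is algebraically the kernel-OPLS model for
linear kernels while making held-out projection direct. The response is a
centred ±1 indicator; only one predictive component exists for a two-class
response (`n_pred` is validated accordingly).

Q² = 1 − PRESS/TSS from stratified 7-fold cross-validation; block kernels,
weights and the model are refitted on every training fold and held-out
samples are projected with training-fold centring/scaling. With n = 10
(5+5) and K = 7, folds are necessarily unequal (1–2 samples); fold
assignment is seed-controlled. If no block has positive RV against a
(typically permuted) training response, the fold falls back to equal
weights rather than failing.

Permutation significance re-runs the full cross-validation under randomly
permuted responses; `perm_p = (1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1)`, plus
a one-sample t-test of the null Q² sample against the observed value. At
n = 10 a random permutation reproduces the observed partition with
probability 2/C(10,5) ≈ 0.8%; such identity partitions are excluded from
the null (they are the observed assignment, not a relabelling), which the
add-one estimator already accounts for.

VIP is computed over the concatenated blocks from the back-projected
predictive loadings p_b = X_bᵀt/(tᵀt): with one predictive component
VIP_j = √P·|w_j|/‖w‖, so RMS(VIP) = 1 identically and transcript and
protein importances share one scale.

**Q² at sparse planted signal.** With 140 planted features among ~4000 and
independent noise, held-out kernel-PLS predictions are shrunk by the
kernel self-similarity term (K_ii ≈ p dominates the training scores), so Q²
plateaus near 0.2–0.35 regardless of effect size; pushing Q² above 0.5
requires roughly 10–25% of features carrying signal (verified against an
independent PLS implementation on identical fixtures). Real omics reach
higher Q² because biological and technical variation is low-rank and
treatment effects are dense, neither of which the clean-noise generator
reproduces. The permutation test, in contrast, is well powered at desk
scale: planted models reach the minimal attainable p.

## Enrichment

The signal2noise score is (μ₁−μ₂)/(σ₁+σ₂) with each σ floored at
max(0.2·|μ|, 0.2). Rankings are strictly ordered (ties broken by feature
id). ES is the signed extreme of the weighted running sum (hit increments
∝ |score|^weight, weight default 1; miss decrements uniform), evaluated at
hit boundaries only — identical to the full walk, and tested against one.
The null is gene-label permutation: one shared label permutation per draw,
a size-m null set being the sorted prefix of each permuted row; NES divides
ES by the mean |null ES| of matching sign, the nominal p is the same-sign
exceedance fraction (add-one smoothed), and q is BH within each
(cell type, layer, ranking) family. Leading-edge ("core enrichment")
members sit at or before the extremum (after, for negative ES).

Term filtering keeps terms with p < 0.05 and q < 0.1 in both omics layers
(under either ranking kind) in at least one cell type. Wang similarity
propagates S-values up the DAG by max-product dynamic programming
(`is_a` 0.8, `part_of` 0.6); distance 1 − similarity feeds average-linkage
clustering with a default cut at 0.5. ORA is the one-sided hypergeometric
upper tail with fold enrichment relative to the universe.

## Biopsy validation

Z-scores are computed per gene across the pooled cohort (donors included),
then averaged over the gene set per sample; the cohort-wide mean of the
score is 0 by construction. Group comparison is one-way ANOVA on the
pathway scores (per-gene testing goes through SAM). SAM uses
d = (μ₁−μ₂)/(s+s₀) with the pooled scatter s; s₀ is chosen from the 0,5,…,
100 percentile grid of s by minimising the coefficient of variation of the
window-wise median absolute deviation of d (windows are s-quantile bins,
up to 100). Per-gene q is the median over permutations of null exceedance
counts divided by the observed count, made monotone in the rank of |d| and
clipped to [0,1]; all group relabellings are enumerated exhaustively when
requested (the 3-vs-3 fixture enumerates all C(6,3)=20). π₀ is not
estimated (conservative). Spearman correlation uses midranks with two-sided
p-values; constant inputs are reported as missing.

## Pipeline and determinism

The orchestrator runs simulate → preprocess → de → copls → select → enrich
→ validate over one output directory; every intermediate is a plain-text
table, each stage can resume from files, and the manifest records config,
seeds, file list and timings. All randomness derives from the single
configured seed (stage-specific sub-seeds are fixed offsets), and reruns
with identical config are byte-identical apart from manifest timings.

Problem sizes used by the test suite and acceptance script — 2000 genes,
4 cell types, 50 null datasets for calibration, 10 (tests) or 3 (script)
recovery replicates, 99 model permutations and 500 enrichment permutations
— are desk-scale choices that keep a full run in minutes while leaving
every statistic's estimator unchanged.

## Known limits

- No voom precision weights: mild conservatism on low-count genes' tests.
- Independent-noise generator: recovery and calibration results bound the
  machinery, not real-data performance; Q² in particular is pessimistic
  relative to low-rank real-world noise (see above).
- Only two-class designs with one predictive component; no multi-class DA.
- GSEA uses gene-label permutation (rankings are precomputed statistics);
  sample-label permutation is out of scope.
- Batch handling is limited to blocking in the linear model; no
  RUV/ComBat-style correction.
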