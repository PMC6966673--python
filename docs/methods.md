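# Methods

This note documents the models and procedures implemented in `raregene`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Expression convention

All analysis runs on log2(TPM + 1). "Detected" always means
log2(TPM + 1) > 0, i.e. TPM > 0. Matrices are genes × cells with unique
string identifiers on both axes; the TPM view and the log view are held by
`ExpressionMatrix`, and the log view is always recomputed from TPM, never
stored separately.

## Quality control (`preprocess`)

Cells are excluded when they have fewer than `min_reads` = 200,000 aligned
reads or fewer than `min_genes` = 3000 detected genes. Both thresholds are
exclusive ("fewer than"), so a cell exactly at a boundary passes.
Protein-coding genes (PCGs) are dropped unless at least
`pcg_min_cells` = 2 cells show log2(TPM+1) strictly above
`pcg_expr_threshold` = 1.0; the "larger than one" bar is read on the log
scale, consistent with the expression convention used everywhere else.
lncRNAs are never touched by this filter — they get their own
noise treatment (below). Both filters are idempotent and invariant to row
and column order.

## Copy-number proxy and malignancy (`cnv`)

Genes are sorted by (chromosome, start), stably; the per-gene copy-number
proxy for a cell is the mean log expression of its `window` = 100 flanking
genes — 50 on each side, the focal gene excluded, truncated at the ends of
the sorted list — after which each cell's vector is centered to mean zero.
The window slides over the single global sort by default; a
`per_chromosome` mode restarts it at chromosome boundaries. Sidedness and
edge handling are a design choice here: flanking counts are split evenly
and windows simply shorten at the edges.

The normal reference averages normal-sample expression per gene first and
then smooths and centers that single vector. Cells plus the reference are
clustered agglomeratively on 1 − Pearson correlation with average linkage,
cut into k = 2 groups; cells sharing the reference's cluster are
non-malignant. Two rows that are both constant are defined to be at
distance 0 (and at the maximal distance 2 from non-constant rows), so a
degenerate profile cannot poison the linkage.

When the cut fails to isolate a reference cluster genuinely smaller than
the whole set, the separation carries no information. With noisy profiles
the failure mode is not "one cluster" but "one cluster plus a stray
outlier cell", so the failure condition is: the reference cluster contains
more than `max_reference_fraction` = 0.9 of the cells. In that case every
cell is flagged malignant, with a warning — the configuration in which
this tool is used is a tumor sample, where non-malignant cells are the
minority. Cells numerically identical to the reference are always
non-malignant.

The window size matters in proportion to the gene count: correlations
between smoothed profiles are effectively computed over ~n_genes/window
independent blocks, so small test matrices (hundreds of genes) use windows
of 20–30 while the 2800-gene default uses 100.

## lncRNA noise filtering (`noise`)

Sporadic low-level lncRNA signal (genomic DNA contamination, incompletely
processed transcripts) is filtered per cell with a two-feature classifier:

* **relative abundance** — the empirical-CDF rank in (0, 1] of the
  lncRNA's expression among all lncRNAs detected in that cell, ties
  sharing the maximal rank;
* **exon coverage** — the externally supplied fraction of the gene's exons
  covered by reads in that cell, validated to [0, 1].

Training labels come from the population: lncRNAs detected in strictly
more than `pos_fraction` = 0.8 of cells are positives (genuinely
expressed); lncRNAs detected in 1–`neg_max_cells` (= 2) cells are
negatives. Membership is fixed on the full QC-passed population and then
intersected with the lncRNAs detected in the focal cell; cells with fewer
than `min_train` = 5 training points in either class are excluded rather
than pooled, since the model is per cell.

Each class gets a bivariate Gaussian KDE (Scott's bandwidth — no kernel or
bandwidth is canonical here, and Scott is the standard default), evaluated
on a 100 × 100 lattice over the unit square; query densities are obtained
by bilinear interpolation on that lattice. The score is
(pos + ε) / (neg + ε) with ε = 1e−10 added to both numerator and
denominator, so the no-information limit (both densities ≈ 0) is a ratio
of 1 rather than an overflow. The decision cutoff is chosen among the
observed ratios to maximize balanced accuracy — (sensitivity +
specificity)/2 — with ties broken toward the smallest cutoff; a
continuous sweep cannot improve on the observed candidates. A ratio
strictly below the cutoff means "noise", at or above means "expressed";
noise entries are zeroed in the denoised matrix, so denoising can never
increase an entry.

Classifier quality is estimated by stratified 5-fold cross-validation
(fold assignment seeded and deterministic): per fold, the KDEs are refit
on the training lncRNAs and the ROC AUC of the ratios is computed on the
held-out ones. Cells are kept only when the mean fold AUC is strictly
above `min_auc` = 0.8. The final classifier applied to all detected
lncRNAs is refit on all training points; cross-validation serves only the
gate.

## Rare-gene identification (`rare`)

Per gene: average non-zero expression (mean of log values over detected
cells; undefined — NaN, never 0 — when the gene is detected nowhere), cell
proportion, detected-cell count, and per-sample detection proportions.

The null: all matrix entries are permuted uniformly over the whole
genes × cells grid, `n_perm` = 1000 times; per permutation the two
statistics are recomputed for every gene and pooled across genes and
permutations (single global thresholds, not per-gene ones). The
expression threshold is the 99th percentile of the pooled expression null;
the proportion threshold is the 1st percentile of the pooled proportion
null. Percentiles interpolate linearly between order statistics. Genes
with no detected entry in a scramble contribute no expression-null value.

A gene is rare iff average non-zero expression > expression threshold,
cell proportion < proportion threshold (both strict), detected in at least
`min_cells` = 10 cells, and at most `max_sample_prop` = 0.2 of any single
sample's cells (failing only when strictly above). Every violated
criterion is recorded (`low_expr`, `high_proportion`, `too_few_cells`,
`abundant_in_sample`), so a call table is self-explanatory.

Shuffle-mode note: a per-gene (row-wise) shuffle would permute each gene's
values across cells and leave both statistics unchanged — a vacuous null.
The sensitivity-analysis alternative exposed as `within-cell` therefore
permutes each cell's column across genes instead, which preserves per-cell
library structure while breaking gene identity.

The simpler quartile screen flags any gene whose average non-zero
expression is strictly above the third quartile (linear-interpolation
convention) of the PCG averages while its cell proportion is strictly
below 0.2, and reports the flagged fraction among all genes above the
quartile bar.

Small-cohort caveat: with only 10–20 cells per sample the per-sample 20%
cap is crossed by 3–4 detected cells, so at toy scale it dominates the
call; the default conditions (75 cells per sample) leave it a rarely
binding sanity filter, which is its intended role.

## Signature scores (`scores`)

Every score is a plain mean of log2(TPM+1) over a gene set, after dropping
duplicate identifiers, genes absent from the matrix, and genes with no
expression in any cell. The stemness score subtracts the per-cell mean
over all genes from the marker mean, making it exactly invariant to adding
a constant to the whole matrix; its significance is judged against
`n_sets` = 1000 random marker sets of the same size drawn from the
expressed genes (the null is centered at zero by construction and narrows
as set size grows). G1/S and G2/M scores are plain set means without any
cell-level standardization. Invasive-potential scores are the four set
means; cells are grouped by Ward clustering on Euclidean distance over the
four standardized score columns, cut at k = 4 (zero-variance columns are
zeroed, so identical cells always share a cluster).

## The synthetic generator (`synthetic`)

The generator produces the regimes the pipeline assumes, with ground
truth. All randomness derives from one seed through named sub-streams
(annotation, gene means, baseline, dropout, rare, noise, coverage,
subpopulations, reads, normals), so changing one component's settings
leaves the other draws untouched.

* **Baseline**: per-gene means μ_g ~ Normal(1.5, 0.75) on the log2 scale;
  cell-level values Normal(μ_g, 0.75) clamped at 0. These defaults give
  the familiar picture of a detected-fraction around one half and a
  right-tailed non-zero expression distribution.
* **Dropout**: an entry is detected with probability
  logistic(steepness · (x − midpoint)), midpoint 1.0 and steepness 2.0 —
  a minimal detection-probability-vs-abundance law that makes detection
  proportions meaningful.
* **Rare genes**: 20 genes (split between PCGs and lncRNAs) are zeroed and
  re-planted with Normal(3.0, 0.3) values — the non-zero mean two baseline
  SDs above the baseline mean — in exactly round(0.05 · n_cells) cells
  drawn from the malignant subset (rare genes are a tumor-cell
  phenomenon). The exact count, rather than a Bernoulli draw, gives
  recovery tests crisp truth.
* **Noise lncRNAs**: 400 lncRNAs carry only 1–2 sporadic entries of
  |Normal(0.6, 0.2)| + 0.05 each, flagged in the ground-truth mask. Exon
  coverage is Beta(8, 2) for genuine entries and Beta(2, 8) for noise
  entries, so coverage separates the classes stochastically.
* **CNV**: malignant cells (240 of 300) receive a +1.0 log2 shift over a
  contiguous window of 300 annotation-adjacent genes, applied to the
  latent expression before dropout — an amplification raises detection
  too. The normal reference shares μ_g plus a per-gene tissue offset of
  SD 0.25 (a normal-tissue bulk profile is a different tissue, not a
  noiseless tumor average), has low sample noise (SD 0.2), no dropout, and
  lacks the rare genes and noise lncRNAs, which are tumor artifacts.
* **Subpopulation**: 30 stem-like cells (within the malignant subset)
  overexpress the emitted stemness (51 genes), G1/S, G2/M (30 each) and
  four invasion sets (30 each) by +1.5 log2 — one planted
  stem-like/cycling/invasive subpopulation, mirroring the coupling of
  those programs in tumor cell subsets.
* **Cell metadata**: aligned reads Uniform{250,000..2,000,000} (all cells
  pass read QC, keeping planted counts exact); cells assigned round-robin
  to 4 samples.

What the generator does **not** emulate: UMI counting, batch effects,
doublets, ambient RNA, gene-length bias, realistic chromosome-scale CNV
breakpoints, or correlated gene programs beyond the planted ones. Passing
recovery tests therefore shows the procedures detect the structure they
define under their own assumptions — not that those thresholds are optimal
on any particular real dataset.

## Problem sizes used in tests and the reproduction script

Recovery experiments run at the default conditions (2000 PCGs + 800
lncRNAs × 300 cells, 1000 permutations) over 20 seeds. The
noise-classifier experiments use a classifier-focused variant (60 cells,
800 lncRNAs, 400 of them noise) because per-cell negative training sets
scale as n_lnc/n_cells — the regime of real data, where lncRNAs far
outnumber cells. Unit tests use a ~500-gene × 60-cell configuration with
CNV windows of 20–30, chosen (see the window note above) so smoothed
profiles retain enough independent blocks. The end-to-end determinism
fixture is 1100 genes × 64 cells with 200 permutations.

## Numerical and reproducibility notes

* Percentile and quantile computations use numpy's linear interpolation
  between order statistics, everywhere.
* The permutation null consumes exactly one `Generator.permutation` call
  per iteration, so an external loop sharing the seed reproduces the
  thresholds bit for bit.
* Per-cell CV seeds derive from (run seed, cell index) via
  `SeedSequence`, making fold assignments independent of which other
  cells are present.
* Manifests embed a SHA-256 hash of the canonical YAML config; two runs
  with one config and seed are byte-identical except the timestamp.
* Degenerate inputs fail loudly: undefined averages are NaN with a reason
  rather than 0, untrainable cells are recorded with their cause, and a
  clustering that cannot separate the reference falls back as described
  above with a warning.

## Known limitations

* The malignancy call assumes non-malignant cells are a minority; on a
  mostly-normal sample the uninformative-cut fallback mislabels cells
  (loudly).
* The noise classifier needs lncRNA counts well above cell counts; small
  panels leave cells untrainable, and those cells are dropped rather than
  rescued by pooling.
* The per-sample abundance cap is meaningful only with tens of cells per
  sample (see the small-cohort caveat above).
* Exon coverage is accepted as an input feature; computing it from
  alignments is upstream of this package.
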