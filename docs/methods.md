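# Methods

## The problem

N6-methyladenosine (m6A) is the most abundant internal mRNA modification and
is strongly cell-type specific, but the standard assay (m6A-seq / MeRIP-seq,
an antibody-based IP of methylated fragments paired with an input library)
only works on bulk populations. This package implements a two-arm strategy
around that limitation:

1. **Winscore arm** — quantify m6A from bulk m6A-seq of sorted cell
   populations by a window-level IP/input enrichment score, producing a
   peaks × samples methylation matrix.
2. **Predictive arm** — learn, per m6A site, a regression from the
   expression of trans-acting m6A regulators (writers, erasers, readers,
   cofactors) and cis sequence features to the site's methylation level.
   Once trained, the model predicts m6A in single cells from ordinary
   scRNA-seq, where no antibody assay is possible.

The biological premise is that cell-type-specific m6A deposition is jointly
determined by trans regulators and cis elements, so regulator expression
carries enough signal to reconstruct site-level methylation.

## Winscore quantification

Each transcript is tiled with sliding windows (width `window_size` = 100 bp,
step 50 bp; five consecutive windows therefore span 300 bp). A trailing
partial window is kept when it is at least one step wide, so the grid covers
the transcript. Per window w with width L_w and library size N:

    RPKM_w = count_w / ((L_w / 10^3) · (N / 10^6))

    winscore_w = (RPKM_IP,w + 1) / (RPKM_input,w + 1)

The +1 pseudo-count on both libraries damps unreliable ratios in poorly
covered windows. Windows with winscore **strictly greater than 2** are
significant; maximal runs of consecutive significant windows within a gene
are merged into peaks, and runs longer than 5 windows are split greedily
left-to-right into chunks of at most 5 (≤ 300 bp), limiting false merges.
A peak's m6A level per sample is the mean (default; max by flag) of its
member windows' winscores.

Two definitions of the winscore circulate: the plain adjusted ratio above,
and a variant that first divides each library's adjusted RPKM by its
within-gene median. The plain ratio is the default; the gene-median variant
is available via `QuantConfig(gene_median_norm=True)`.

Expression matrices accompanying m6A-seq (TPM-scale) can be quantile
normalized across samples (`tpm_quantile_normalize`): every column is mapped
onto the per-rank means of the sorted columns, fractional (tied) ranks
interpolating between adjacent reference values.

Peak matrices from different window grids are compared with
`match_windows`: rows are paired within genes by genomic overlap, greedily
by decreasing overlap length, each row used once.

## Feature construction and cleaning

- **Missing-value rule.** Rows, then columns, with a missing fraction
  *strictly greater than* 10% are removed; both fractions are computed on
  the original matrix, making the two passes order-symmetric. The operation
  is idempotent.
- **Cell QC** (scRNA-seq raw counts): keep cells with 200 < detected genes
  < 4000, 200 < total counts < 20 000 and mitochondrial fraction < 25%;
  then drop genes detected in fewer than 3 remaining cells.
- **Normalization.** Per cell, counts are scaled to 10 000 and log1p
  transformed (rank-preserving within each cell).
- **Trans features.** The expression matrix is restricted to the regulator
  panel, in panel order (the reference panel comprises 593 regulators;
  any list can be supplied). Panel genes absent from the data become zero
  columns and are flagged — scRNA-seq panels routinely lack genes, and an
  auditable zero is preferable to a hard failure. Whether regulator
  expression enters the models raw, library-normalized or log1p is
  configurable; the default is log1p-harmonized values.
- **Cis features.** Each site's sequence context is summarized by position
  probability matrices (PPMs; the reference set has 42 motifs around a
  GGACU/DRACH core). Two encodings: `flatten` emits the site's own 4×L PPM
  as a row-major vector (constant per site, hence only informative for
  models that pool across sites), and `score` emits, per motif, the maximum
  log2 likelihood ratio of the motif versus a uniform background over the
  site sequence — usable in both model modes.
- **Ortholog mapping.** For cross-species comparison, gene ids are relabeled
  through a many-to-one table; unmapped genes are dropped (and reported),
  several sources mapping to one target are summed (counts are additive;
  max by flag), and the result is log1p-harmonized.

## Models

Five regressor families are supported: random forest (`rf`), linear
regression (`lr`), k-nearest neighbours (`knn`), linear support-vector
regression (`linear_svr`) and polynomial-kernel SVR (`svr_poly`), all via
scikit-learn. Observations are split 70/30 into train/test (seeded);
hyperparameters are chosen by exhaustive grid search under 5-fold
cross-validated mean R², ties resolved in grid order. Default grids:
rf {trees 100/300/500 × depth ∞/10/20}, knn {k 3/5/10},
svr_poly {degree 2/3 × C 0.1/1/10}, linear_svr {C 0.1/1/10}, lr {—}.

Two training modes exist because per-site ROC evaluation and a cis-only
model pull in different directions:

- `per_site` (default): one regressor per m6A site on the trans features —
  cis features are constant within a site and are omitted.
- `global`: a single regressor over stacked (site, cell) rows whose feature
  vector is the trans features concatenated with the site's cis features.

Targets may be modelled on the identity scale or as log2(1+y) (inverted at
prediction). Model bundles persist as a JSON manifest (family, mode,
hyperparameters, feature list with SHA-256 hash, seed, format version) plus
joblib-serialized regressors; loading verifies version and hash and
reproduces bitwise-identical predictions.

## Evaluation

- **R²** = 1 − SSE/SST per site on held-out cells.
- **Tolerance labels**: a prediction is "correct" when |ŷ − y| ≤ 0.5
  (inclusive). The 0.5 tolerance applies on the model's target scale.
- **AUROC** is computed on a matched-vs-resampled pool: the n true
  (truth, prediction) pairs are positives, n seeded random re-pairings are
  negatives, and every pair is scored by −|prediction − truth|. AUROC is
  the Mann–Whitney rank statistic of those scores against the pool labels,
  so an accurate model approaches 1 while any permuted pairing gives 0.5.
  This construction was chosen because scoring resampled pairs by their own
  error *and* labelling them by a threshold of that same error is
  degenerate (AUROC ≡ 1); discriminating true pairings from random ones is
  the well-defined counterpart that preserves the resampling idea. It is
  seeded and isolated in one operation (`auroc_tolerance`).
- **Balanced accuracy** = (sensitivity + specificity)/2 on labels; when
  derived from scores it is the maximum over ROC thresholds of the pooled
  curve.
- **Permutation nulls**: any pairing-dependent metric is recomputed under
  seeded shuffles of the prediction order; the empirical p uses the +1
  correction, (1 + #{null ≥ observed}) / (1 + n_valid), so p is never 0.
- **Correlation**: Pearson by default (Spearman by flag), pairwise deletion
  of missing values, two-sided p.
- Metric distributions across sites are non-normal, so summaries report
  median and quartiles.
- **Metagene profile**: peak midpoints are mapped to the 5′UTR, CDS or
  3′UTR of their transcript, rescaled to [0,1) within the region, and
  binned into 10 bins per region (30 bins, 5′UTR first); the profile is
  normalized to sum 1 and unmappable peaks are counted separately.
  Midpoint assignment (rather than span-weighting) is the simplest faithful
  summary of peak positions.

## Synthetic data: what it emulates and what it does not

The simulator creates the minimal statistical structure the method assumes:

- Regulator expression is i.i.d. log-normal, log(x) ~ N(1.0, 1.0) by
  default — the heavy right tail of TPM-scale data. Bernoulli dropout is
  available but off by default.
- A sparse planted network drives each site by `regulators_per_site` = 3
  regulators with coefficients ~ N(0, 0.8) acting on log1p expression, plus
  a site intercept ~ U(1,3) offset by 3·Σ max(0, −coef) so that levels stay
  positive; ground-truth levels add N(0, noise_sd = 0.1) noise and are
  clipped at 0 (a safeguard that is essentially never active at defaults).
- The m6A-seq arm draws Poisson window counts with per-transcript
  log-normal expression weights scaled to a 10^6-read library; IP rates are
  multiplied by `enrichment_fold` = 4 in proportion to a window's overlap
  with planted 300-bp peak spans placed near stop codons (the canonical
  m6A hotspot). Library sizes report realized totals, so counts are
  conserved by construction.
- PPMs are Dirichlet-like perturbations around an IUPAC consensus
  (GGACU; 42 motifs by default).

Not emulated: ambient RNA, doublets, UMI chemistry, fragmentation bias,
positional coverage decay, regulator–regulator correlation, or any
nonlinearity in the true regulatory map. Passing tests therefore show that
the pipeline recovers planted linear-on-log structure under Poisson/Gaussian
noise — not that real m6A levels are predictable to the same degree; on
real data accuracy is bounded by the fidelity of the training corpus.

Default simulated study sizes (1000 cells; 593 regulators; 100 sites;
50 transcripts) keep every experiment at desk scale while preserving the
regulator-panel and motif-set structure of the reference inputs; the
recovery and null-control experiments use 100 regulators / 50 sites so that
per-site forests stay cheap. Site counts in real corpora (thousands) are
corpus-specific and carry no additional structure the tests would exercise.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; BED on disk.
- All stochastic stages (generators, splits, CV folds, forests, permutation
  and resampling draws) consume explicit seeds; pipeline reruns with the
  same config are byte-identical.
- Peak splitting is greedy left-to-right — deterministic and order-stable;
  only the ≤ 5-window constraint is inherent.
- Grid-search ties break toward the earlier candidate in grid order.
- Degenerate cases: constant targets warn and fit a constant predictor;
  zero-variance truth makes R² (and correlation) an explicit error rather
  than a silent NaN; single-class ROC pools raise "AUROC undefined";
  single-column quantile normalization warns and no-ops.
- `filter_missing` erroring when everything would be dropped, and QC
  erroring when no cell survives, are deliberate: silent empty matrices
  propagate confusing failures downstream.

## Known limitations

- The per-site mode needs every site observed across training cells;
  sites with entirely missing targets are skipped and reported, not imputed.
- The ROC construction is one principled reading of an underdetermined
  protocol; absolute AUROC values are comparable within this package, not
  across tools.
- `svr_poly` and `linear_svr` scale poorly beyond a few thousand training
  observations; the default family is `rf`.
- The winscore arm assumes the window grid matches between IP and input
  libraries and does not model fragment-length effects.
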