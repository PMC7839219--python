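# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic-data tests do and do not establish.

## FDR from posterior error probabilities

The inputs carry per-PSM posterior error probabilities (PEPs), optionally
updated by retention-time evidence (consumed as a column; the updating
algorithm itself is out of scope). The expected false discovery rate of
accepting every PSM up to a PEP threshold is the mean PEP of the accepted
set, so q-values are computed by sorting PEPs ascending, taking running
means, and then the running minimum from the most permissive threshold
down. Tied PEPs all receive the estimate at the tie's last rank, so equal
scores get equal q-values. Peptide-level FDR is computed over unique
peptide sequences, each scored by its best (minimum) PSM PEP; protein-level
FDR uses the best-peptide rule — each protein represented by its single
most confident peptide — which avoids the accumulation of marginal peptide
evidence onto long proteins. Both filters are applied dataset-wide at
alpha = 0.01 by default.

## Filtering chain and ledger

Steps run in a fixed order: minimum-PSM run filter (default 500; removes
failed injections/preps), peptide+protein FDR, reverse/contaminant removal,
then in "stringent" mode the PIF filter (default ≥ 0.8; rows with missing
PIF are removed because purity cannot be certified) and the carrier-ratio
filter (mean single-cell reporter intensity ≤ 10% of the carrier;
cross-labeled or contaminated peptides have implausibly high single-cell
signal). The carrier-ratio mean is over observed single-cell channels only;
PSMs with no observed single-cell values are kept (ratio undefined) and
PSMs with zero/missing carrier are dropped. A ledger row (runs, cells,
proteins, peptides, PSMs) is appended after every step, and the matrix-level
steps (cell QC, ≥ 15-cell filters) extend the same ledger downstream. The
chain is idempotent on its own output provided surviving runs stay above
the minimum-PSM threshold.

## Cell quality control

Different peptides of one protein should report consistent relative levels
for a real cell. Reporter intensities are first turned into fold changes
relative to the peptide's mean over the set's single-cell and control
wells (both well types are scored on equal footing; carrier and reference
channels are excluded because their 200×/5× scale would dominate the
mean — the channel set is configurable). Per cell, the CV (sample sd /
mean, n−1 denominator because peptide counts are small) is computed for
each protein with at least 6 observed peptides ("more than 5"), and the
median CV over qualifying proteins is the QC statistic. Control wells
receive only coisolation background that is independent between peptides,
so their median CV is high; wells are kept when their median CV is below
the threshold (default 0.365). Control wells are never kept; a control
below the threshold is flagged as suspect (likely contamination or
cross-labeling). Note the threshold direction: low CV = consistent
quantification = good cell. Exact scale-invariance of the median CV holds
for a common factor on a whole set; a factor on a single cell's column
cancels in that cell's sd/mean but re-enters weakly through the peptide
means.

## Normalization, imputation, batch correction

The order of operations is fixed: reference-channel division (per set) →
column/median division → row/mean division → ≥ 15-cell peptide filter →
log2 → peptide-to-protein collapse by median → column-median then
row-median subtraction → ≥ 15-cell protein filter → kNN imputation → batch
correction. Missing values are ignored (never zero-filled) in every mean,
median and distance; a peptide whose reference value is missing or zero in
a set loses its values in that set, since nothing anchors them across sets.

kNN imputation (k = 3) uses Euclidean distance between cells computed over
the proteins observed in both, rescaled by √(n_total/n_shared) so that
sparse overlaps are not spuriously close. Each missing entry becomes the
mean of the k nearest cells' observed values for that protein; if none of
the k neighbors observed it, the entry stays missing, and downstream
correlation steps fill such residual holes with the protein mean (the
neutral value on the centered scale).

Batch correction is location–scale per protein, sequentially for run and
TMT channel: center within batch, then rescale the batch residual sd to
the pooled sd. Raw per-batch variances from the handful of cells a single
channel contributes are far too noisy to divide by, so batch variances are
shrunk toward the pooled variance with 10 pseudo-observations before
scaling; batches of size one are centered only. The batch keys are
pluggable (any column of the design's cell metadata). The correction
assumes cell types are randomized over channels — in a confounded design,
channel centering removes biology, which is why the synthetic design
shuffles cell positions per run.

## Weighted PCA and spectral ordering

Protein weights are w_i = r_i · r_i, the squared norm of protein i's vector
of Pearson correlations to all proteins (the self-correlation is included;
it adds the same +1 to every weight). PCA is performed on the cell × cell
Pearson correlation matrix of the weighted data; cell scores are its
eigenvectors and variance fractions are eigenvalues over the trace.
Eigenvector signs are fixed by making the largest-magnitude coordinate
positive. Zero-variance proteins are dropped with a warning.

Spectral ordering builds cell–cell weights w_ij = Pearson + 1 (entries in
[0, 2], always connected), the Laplacian L = D − W, and sorts cells by the
Fiedler vector (unit eigenvector of the second-smallest eigenvalue, which
minimizes vᵀLv = ½ Σ w_ij (v_i − v_j)² among unit vectors orthogonal to the
constant vector). The sign is fixed by requiring the first cell in id order
to have a non-negative entry; an eigenvalue gap below 1e−9 triggers a
deterministic fallback to cell-id order with a warning. The two-way
spectral split is the sign of the Fiedler entries.

## Ion-count statistics

One unit of reporter-ion S/N on an Orbitrap corresponds to 3.5 ions at a
resolving power of 240,000, scaling with the square root of the
resolving-power ratio: factor(RP) = 3.5·√(240000/RP), ≈ 6.48 at 70,000.
Two conversion modes are exposed: `continuous` multiplies by the exact
factor; `reported` rounds the factor to the nearest integer first
(6.48 → 6), matching the commonly quoted arithmetic (S/N 50 → 300 ions).
The 6-vs-6.5 discrepancy is inherent to the calibration as published; both
modes are kept rather than reconciled. Ion counts are Poisson, so the
relative counting error of n sampled copies is 1/√n.

## Joint RNA–protein covariation

For each gene shared between modalities, r_i and p_i are its vectors of
Pearson correlations to all other shared genes in the RNA and protein data
(self-correlations excluded — they are identically 1 and would inflate
agreement), and ρ_rp = Pearson(r_i, p_i). The null permutes the gene
alignment between modalities. The typically bimodal ρ_rp distribution is
split with a 2-component Gaussian mixture: the higher-mean component is
cluster 1 (concordant covariation), the lower is cluster 2 (opposite
covariation); genes are assigned at posterior ≥ 0.75, otherwise left
unassigned. The distribution is declared unimodal — no clusters — when the
component means are closer than 0.15 or Ashman's D (separation over
within-mode spread) is below 3; a single Gaussian split in two lands near
D ≈ 2, real modes far higher.

Common PCA takes the leading unit eigenvector of R_r + R_p; a degenerate
leading eigenvalue is an error because the common axis is then not
identifiable. The axis orientation is fixed by positive correlation with
the protein modality's own PC1. Cells are paired across modalities by rank
of their CPC1 scores (equal counts required — the caller subsamples),
with B's axis flipped if the score vectors anti-align, and ties broken by
cell id. Regulon analysis correlates TF abundance (protein and RNA) with
each target's RNA across paired cells and compares activated- vs
repressed-target correlation distributions with a two-sided Mann–Whitney
test (chosen as a robust two-sample test; at least 3 quantified targets
per side, otherwise reported as underpowered). Welch's unequal-variance
t-test is used for bulk marker derivation; gene-set enrichment uses a
two-sample Kolmogorov–Smirnov test of set members against the background
with Benjamini–Hochberg adjustment across sets and the set's mean
abundance as effect size.

## Synthetic data: what it emulates, and what it does not

The generator draws, per protein, a baseline log2 abundance (N(6, 1.5),
spanning the wide dynamic range of cellular proteomes), a
macrophage-vs-monocyte log2 fold change (N(0, 0.8), applied half up/half
down), and for ~30% of proteins a polarization coefficient (N(0, 0.8))
multiplying each macrophage-like cell's latent coordinate g ~ U(−1, 1) —
the 1-D continuum the spectral ordering should recover. A per-gene
modality sign (−1 for ~15% of genes) anti-couples the protein response
from the latent (RNA-side) state, creating the opposite-covariation gene
cluster. Proteins carry 1–8 peptides with log-normal ionization
efficiencies.

Per run, a top-fraction (60%) of peptides is detected by
abundance-weighted noisy ranking, reproducing DDA's run-to-run missingness.
Reporter intensity = channel size (carrier 200, reference 5, cell 1,
control 0) × protein abundance × peptide efficiency × log-normal noise
(σ = 0.25 on the natural-log scale, giving single-cell within-protein CVs
around 0.25) plus an additive exponential coisolation background at 10% of
the expected single-cell signal — consistent with the few-percent
impurities implied by PIF ≈ 0.97 spectra, and i.i.d. across peptides so
control wells have high within-protein CV. Ion counts are Poisson at the
intended copy number; a zero draw is a missing value; S/N = ions / factor.
PEPs mix Beta(1, 99) (correct) with Uniform (5% incorrect, truth-labeled);
PIF sits near 1 (Beta(18, 1)) with a 5% contaminated tail and 2% missing;
2% reverse and 1% contaminant rows and 2% carrier-cross-labeled peptides
exercise the corresponding filters. Default scale is 3000 proteins and
20 sixteen-plex runs (carrier, reference, 10 macrophage-like and 3
monocyte single cells, 1 control, 1 unused, with positions randomized per
run), generating in a couple of seconds.

RNA counts are negative-binomial (dispersion θ = 2) with per-cell size
factors and means proportional to the same latent abundances at a depth
chosen so per-gene copies are roughly 20-fold below the protein ion-copy
scale. Separate compact generators produce paired normalized matrices with
known covariation-cluster labels and an activator-TF regulon scenario for
the joint-analysis tests.

Not emulated: chromatography (elution profiles, apex sampling), isotopic
impurity spillover between TMT channels, peptide-specific digestion or
modification effects, true decoy score distributions, ambient RNA or
doublets. Passing tests therefore demonstrate that the algorithms recover
the structure this generative model encodes at realistic noise — not that
they are robust to every artifact of real instruments.

## Problem sizes in the test suite

Unit tests use one- or few-run designs with hundreds of proteins. The
end-to-end recovery checks use the full 20-run default design with 1000
proteins — enough for batch sizes to be realistic and for ~260 single
cells — and the multi-seed control-vs-cell QC check uses 50 independent
2-run simulations. The permutation null uses 100 genes × 1000
permutations. These sizes are the package's own choice of a compact but
representative regime; all scale parameters are exposed.

## Known limitations

- The filter chain is idempotent only while surviving runs keep ≥ min_psms
  PSMs after FDR filtering.
- Location–scale batch correction removes any protein-level mean difference
  that is confounded with a batch key; it is only appropriate for
  randomized designs. A ComBat-style empirical-Bayes strategy can be
  plugged in via the batch-key interface but is not shipped.
- `pair_cells_by_rank` assumes both score vectors order cells along the
  same biological axis; the anti-alignment fix uses the entrywise
  correlation of the two score vectors, which is a convention, not a test.
- The reported-mode ion conversion is intentionally coarse (integer
  factor); use continuous mode for quantitative downstream modeling.
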