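"""Normalization chain, protein collapse, min-cell filters, kNN imputation
and batch correction for the peptide/protein quant matrices.

Order of operations: reference-channel division -> column median division ->
row mean division -> (>= min-cell peptide filter) -> log2 -> collapse peptides
to proteins by median -> column-median and row-median subtraction ->
(>= min-cell protein filter) -> kNN imputation -> batch correction. Missing
values are ignored (never zero-filled) in every statistic and distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import PsmTable, QuantMatrix, SetDesign

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    min_psms: int = 500
    fdr_alpha: float = 0.01
    min_pif: float = 0.8
    max_carrier_ratio: float = 0.1
    min_cells_per_peptide: int = 15
    min_cells_per_protein: int = 15
    knn_k: int = 3
    cv_threshold: float = 0.365
    min_peptides_per_protein_cv: int = 6
    batch_keys: tuple[str, ...] = ("run", "channel")

    def __post_init__(self):
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        for name in ("min_cells_per_peptide", "min_cells_per_protein"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def reference_ri(psm: PsmTable) -> pd.DataFrame:
    """Peptide x run matrix of reference-channel intensities (median per PSM)."""
    frames = {}
    for run_id, sub in psm.df.groupby("run_id", sort=False):
        refs = psm.design[run_id].by_role("reference")
        if not refs:
            continue
        frames[run_id] = sub.groupby("sequence")[f"ri_{refs[0].label}"].median()
    return pd.DataFrame(frames)


def normalize_peptides(
    m: QuantMatrix, design: SetDesign, reference: pd.DataFrame
) -> QuantMatrix:
    """Reference-channel division, then column-median and row-mean division.

    ``reference`` is the peptide x run matrix from :func:`reference_ri`.
    Peptides with a missing or zero reference value in a set lose their
    values in that set (there is nothing to merge them against).
    """
    values = m.values.copy()
    meta = design.cell_meta()
    run_of = meta["run_id"]
    n_lost = 0
    for col in values.columns:
        run_id = run_of.get(col)
        ref = reference[run_id] if (run_id in reference.columns) else None
        if ref is None:
            values[col] = np.nan
            n_lost += int(m.values[col].notna().sum())
            continue
        r = ref.reindex(values.index)
        r = r.where(r > 0)
        before = values[col].notna()
        values[col] = values[col] / r
        n_lost += int((before & values[col].isna()).sum())
    if n_lost:
        log.info("reference normalization removed %d values (missing/zero reference)", n_lost)
    out = m.advance(values, "reference_normalized")

    values = out.values / out.values.median(axis=0, skipna=True)
    values = values.div(values.mean(axis=1, skipna=True), axis=0)
    return out.advance(values, "normalized")


def log2_transform(m: QuantMatrix) -> QuantMatrix:
    values = m.values.where(m.values > 0)
    n_bad = int((m.values <= 0).sum().sum())
    if n_bad:
        log.info("log2: %d nonpositive values set to missing", n_bad)
    return m.advance(np.log2(values), "log2")


def collapse_to_proteins(m: QuantMatrix, peptide_to_protein: pd.Series) -> QuantMatrix:
    """Protein x cell matrix: per protein per cell, median over observed peptides."""
    proteins = peptide_to_protein.reindex(m.values.index)
    values = m.values.groupby(proteins, sort=True).median()
    values.index.name = "protein"
    return m.advance(values, "collapsed", level="protein")


def renormalize_protein(m: QuantMatrix) -> QuantMatrix:
    """Subtract column medians then row medians (log2 scale)."""
    values = m.values - m.values.median(axis=0, skipna=True)
    values = values.sub(values.median(axis=1, skipna=True), axis=0)
    return QuantMatrix(values, level=m.level, state=m.state)


def filter_min_cells(m: QuantMatrix, min_cells: int) -> QuantMatrix:
    """Drop features observed in fewer than ``min_cells`` cells."""
    keep = m.values.notna().sum(axis=1) >= min_cells
    return QuantMatrix(m.values[keep], level=m.level, state=m.state)


def knn_impute(m: QuantMatrix, k: int = 3) -> QuantMatrix:
    """k-nearest-neighbor imputation over cells with Euclidean distance.

    Distances between two cells are computed over the features observed in
    both and rescaled by sqrt(n_features / n_shared) so sparser overlaps are
    not spuriously close. Each missing entry becomes the mean of the cell's
    k nearest neighbors' observed values for that feature; if none of the k
    neighbors observed it, the entry stays missing. Cells sharing no features
    with any other cell are left untouched (logged).
    """
    X = m.values.to_numpy(dtype=float)
    n_feat, n_cells = X.shape
    obs = ~np.isnan(X)
    # pairwise rescaled distances
    D = np.full((n_cells, n_cells), np.inf)
    for i in range(n_cells):
        shared = obs[:, i][:, None] & obs[:, i + 1:]
        diffs = X[:, i][:, None] - X[:, i + 1:]
        diffs = np.where(shared, diffs, 0.0)
        n_shared = shared.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.sqrt((diffs**2).sum(axis=0)) * np.sqrt(n_feat / n_shared)
        d[n_shared == 0] = np.inf
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    out = X.copy()
    n_isolated = 0
    for j in range(n_cells):
        order = np.argsort(D[:, j], kind="stable")
        order = order[np.isfinite(D[order, j])]
        if order.size == 0:
            if (~obs[:, j]).any():
                n_isolated += 1
            continue
        nbrs = order[:k]
        missing = np.flatnonzero(~obs[:, j])
        if missing.size == 0:
            continue
        vals = X[np.ix_(missing, nbrs)]
        have = ~np.isnan(vals)
        counts = have.sum(axis=1)
        sums = np.where(have, vals, 0.0).sum(axis=1)
        imputed = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out[missing, j] = imputed
    if n_isolated:
        log.info("knn_impute: %d cells share no features with any other cell", n_isolated)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.advance(values, "imputed")


def batch_correct(
    m: QuantMatrix,
    design: SetDesign,
    keys: tuple[str, ...] = ("run", "channel"),
    prior_df: float = 10.0,
) -> QuantMatrix:
    """Location-scale batch correction, sequentially per batch key.

    Per feature: center within each batch, then rescale each batch's
    residual standard deviation to the feature's pooled standard deviation.
    Batch variances are shrunk toward the pooled variance with ``prior_df``
    pseudo-observations before scaling — with the few cells a single TMT
    channel contributes, raw per-batch variances are too noisy to divide by.
    Batches of size 1 are centered only. The default keys are the run id and
    the TMT channel; other keys (any column of the design's cell metadata,
    e.g. ``plate``) plug in the same way.
    """
    meta = design.cell_meta()
    key_col = {"run": "run_id", "channel": "channel", "plate": "plate"}
    values = m.values.copy()
    for key in keys:
        col = key_col.get(key, key)
        labels = meta[col].reindex(values.columns)
        corrected = values.copy()
        pooled_var = values.var(axis=1, ddof=1, skipna=True)
        for _, cols in labels.groupby(labels).groups.items():
            cols = [c for c in values.columns if c in set(cols)]
            block = values[cols]
            centered = block.sub(block.mean(axis=1, skipna=True), axis=0)
            if len(cols) > 1:
                var = centered.var(axis=1, ddof=1, skipna=True)
                n_b = centered.notna().sum(axis=1)
                shrunk = (n_b * var + prior_df * pooled_var) / (n_b + prior_df)
                scale = np.sqrt(pooled_var / shrunk)
                scale = scale.replace([np.inf, -np.inf], 1.0).fillna(1.0)
                centered = centered.mul(scale, axis=0)
            else:
                log.info("batch_correct: batch of size 1 for key %s; centered only", key)
            corrected[cols] = centered
        values = corrected
    return m.advance(values, "batch_corrected")


def process_matrix(
    peptide_matrix: QuantMatrix,
    psm: PsmTable,
    design: SetDesign,
    config: PipelineConfig | None = None,
) -> tuple[QuantMatrix, QuantMatrix]:
    """Full chain from a raw single-cell peptide matrix to the protein matrix.

    Returns ``(peptide_normalized, protein_final)``.
    """
    cfg = config or PipelineConfig()
    ref = reference_ri(psm)
    pep = normalize_peptides(peptide_matrix, design, ref)
    pep = filter_min_cells(pep, cfg.min_cells_per_peptide)
    logged = log2_transform(pep)
    prot = collapse_to_proteins(logged, psm.peptide_to_protein())
    prot = renormalize_protein(prot)
    prot = filter_min_cells(prot, cfg.min_cells_per_protein)
    prot = knn_impute(prot, cfg.knn_k)
    prot = batch_correct(prot, design, cfg.batch_keys)
    return pep, prot
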