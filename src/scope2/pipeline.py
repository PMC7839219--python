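"""End-to-end pipeline: PSM filtering -> cell QC -> matrices -> PCA.

Glues the per-module operations together in the published order and keeps
extending the filter ledger through the matrix-level steps (cell removal,
min-cell protein filter) so the whole filtration history reads as one table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import cell_qc, filtering, matrix as mx, structure
from .data_model import PsmTable, QuantMatrix, SetDesign


@dataclass
class PipelineResult:
    psm: PsmTable
    ledger: filtering.FilterLedger
    qc_report: pd.DataFrame
    kept_cells: list[str]
    peptide_matrix: QuantMatrix
    protein_matrix: QuantMatrix
    pca: structure.PcaResult
    cell_meta: pd.DataFrame


def run_pipeline(
    psm: PsmTable,
    design: SetDesign,
    config: mx.PipelineConfig | None = None,
    mode: str = "stringent",
) -> PipelineResult:
    cfg = config or mx.PipelineConfig()
    psm_f, ledger = filtering.run_filter_pipeline(
        psm,
        design,
        mode=mode,
        min_psms=cfg.min_psms,
        alpha=cfg.fdr_alpha,
        min_pif=cfg.min_pif,
        max_carrier_ratio=cfg.max_carrier_ratio,
    )

    # cell QC on relative peptide intensities of single cells + controls
    qc_matrix = psm_f.to_quant_matrix(roles=("single_cell", "control"))
    rel = cell_qc.relative_ri(qc_matrix, design)
    qc = cell_qc.cell_median_cv(
        rel, psm_f.peptide_to_protein(), design, cfg.min_peptides_per_protein_cv
    )
    kept, report = cell_qc.select_cells(qc, cfg.cv_threshold)

    meta = design.cell_meta()
    runs_kept = set(meta.loc[kept, "run_id"]) if kept else set()
    psm_cells = psm_f.replace(psm_f.df[psm_f.df["run_id"].isin(runs_kept)])
    counts = psm_cells.counts()
    counts["cells"] = len(kept)
    ledger.append_counts(
        f"remove cells with median CV above {cfg.cv_threshold:g}", counts
    )

    raw_pep = psm_cells.to_quant_matrix(roles=("single_cell",))
    raw_pep = QuantMatrix(raw_pep.values[kept], level="peptide", state="raw")
    pep, prot = mx.process_matrix(raw_pep, psm_cells, design, cfg)

    p2p = psm_cells.peptide_to_protein()
    final_counts = {
        "runs": counts["runs"],
        "cells": int(prot.values.shape[1]),
        "proteins": int(prot.values.shape[0]),
        "peptides": int(p2p.reindex(pep.feature_ids).isin(prot.feature_ids).sum()),
        "psms": int(
            psm_cells.df["sequence"].isin(set(pep.feature_ids)).sum()
        ),
    }
    ledger.append_counts(
        f"remove features quantified in less than {cfg.min_cells_per_protein} cells",
        final_counts,
    )

    pca = structure.weighted_pca(prot)
    cell_annot = meta.reindex(prot.cell_ids).join(report[["median_cv", "n_proteins_used"]])
    return PipelineResult(
        psm=psm_cells,
        ledger=ledger,
        qc_report=report,
        kept_cells=kept,
        peptide_matrix=pep,
        protein_matrix=prot,
        pca=pca,
        cell_meta=cell_annot,
    )
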