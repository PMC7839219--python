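"""Per-cell quality control from the consistency of relative quantification.

Different peptides of one protein should report similar fold changes for a
cell. Wells that truly received a cell therefore show a low coefficient of
variation (CV = sd/mean) across a protein's peptides, while control wells —
which received reagents but no cell, so their reporter signal is coisolation
background, uncorrelated between peptides — show a high CV. The median CV
over proteins (quantified with more than ``min_peptides - 1`` peptides in
that well) is the QC statistic; wells above the threshold are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import QuantMatrix, SetDesign


@dataclass
class CellQC:
    cell_id: str
    role: str
    median_cv: float  # NaN when no protein qualifies
    n_proteins_used: int
    passed: bool


def relative_ri(
    peptide_matrix: QuantMatrix,
    design: SetDesign,
    roles: tuple[str, ...] = ("single_cell", "control"),
) -> QuantMatrix:
    """Within each set, divide every peptide row by its mean over the set's wells.

    The mean is taken over observed values of the ``roles`` channels
    (single cells and controls by default, putting both well types on equal
    footing), yielding fold changes relative to the set mean. All-missing
    rows stay all-missing.
    """
    values = peptide_matrix.values
    out = values.copy()
    meta = design.cell_meta()
    cols_by_run = meta.loc[meta.index.isin(values.columns) & meta["role"].isin(roles)]
    for run_id, sub in cols_by_run.groupby("run_id", sort=False):
        cols = [c for c in values.columns if c in set(sub.index)]
        if not cols:
            continue
        block = values[cols]
        out[cols] = block.div(block.mean(axis=1, skipna=True), axis=0)
    return QuantMatrix(out, level="peptide", state=peptide_matrix.state)


def cell_median_cv(
    rel_matrix: QuantMatrix,
    peptide_to_protein: pd.Series,
    design: SetDesign,
    min_peptides: int = 6,
) -> list[CellQC]:
    """Median (over proteins) CV of relative peptide values, per well.

    Only proteins with at least ``min_peptides`` observed peptides in the
    well contribute (the ">5 peptides" rule). CV uses the sample standard
    deviation (n-1), appropriate for the small peptide counts involved.
    """
    values = rel_matrix.values
    proteins = peptide_to_protein.reindex(values.index)
    meta = design.cell_meta()
    out = []
    grouped = values.groupby(proteins, sort=False)
    n_obs = grouped.count()  # protein x cell observed-peptide counts
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    cv = (sd / mean).where(n_obs >= min_peptides)
    for cell in values.columns:
        role = meta.loc[cell, "role"] if cell in meta.index else "single_cell"
        cvs = cv[cell].dropna()
        med = float(np.median(cvs)) if len(cvs) else float("nan")
        out.append(
            CellQC(
                cell_id=cell,
                role=role,
                median_cv=med,
                n_proteins_used=int(len(cvs)),
                passed=False,  # set by select_cells
            )
        )
    return out


def select_cells(
    qc: list[CellQC], cv_threshold: float = 0.365
) -> tuple[list[str], pd.DataFrame]:
    """Keep single-cell wells whose median CV is below the threshold.

    Control wells are never kept; controls that nonetheless fall below the
    threshold are flagged as suspect (possible contamination or
    cross-labeling) in the report. Wells with no QC value are removed.
    """
    kept = []
    rows = []
    for c in qc:
        ok = (
            c.role == "single_cell"
            and np.isfinite(c.median_cv)
            and c.median_cv < cv_threshold
        )
        c.passed = ok
        if ok:
            kept.append(c.cell_id)
        rows.append(
            {
                "cell_id": c.cell_id,
                "role": c.role,
                "median_cv": c.median_cv,
                "n_proteins_used": c.n_proteins_used,
                "passed": ok,
                "suspect_control": c.role == "control"
                and np.isfinite(c.median_cv)
                and c.median_cv < cv_threshold,
            }
        )
    columns = ["cell_id", "role", "median_cv", "n_proteins_used", "passed", "suspect_control"]
    return kept, pd.DataFrame(rows, columns=columns).set_index("cell_id")
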