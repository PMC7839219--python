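"""Readers and writers for the external file formats.

Supported inputs: MaxQuant ``evidence.txt``-style PSM tables (tab- or
comma-separated), a YAML or CSV channel-design config, RNA count matrices
(MatrixMarket with gene/barcode sidecars, or dense CSV), and a 3-column
regulon table. Outputs follow the released-data layout: ``Peptides-raw.csv``,
``Proteins-processed.csv`` and ``Cells.csv`` (ids first, then one column per
single cell).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .data_model import (
    Channel,
    DesignError,
    FormatError,
    PsmTable,
    QuantMatrix,
    RegulonTable,
    RunDesign,
    SetDesign,
)

log = logging.getLogger(__name__)

#: evidence column -> internal name. MaxQuant headers on the left.
EVIDENCE_COLUMNS = {
    "Sequence": "sequence",
    "Leading razor protein": "leading_razor_protein",
    "Raw file": "run_id",
    "PEP": "pep",
    "dart_PEP": "pep_updated",
    "PIF": "pif",
    "Retention time": "rt",
    "Reverse": "is_reverse",
    "Potential contaminant": "is_contaminant",
}
REQUIRED_EVIDENCE = ("Sequence", "Leading razor protein", "Raw file", "PEP")

RI_PREFIX = "Reporter intensity"
SNR_PREFIX = "Reporter S/N"


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _reporter_columns(columns, prefix: str) -> list[str]:
    """Reporter columns matched by ordered numeric suffix under ``prefix``.

    Excludes MaxQuant's 'corrected'/'count' variants of the intensity columns.
    """
    pat = re.compile(rf"^{re.escape(prefix)}\s+(\d+)$")
    hits = [(int(m.group(1)), c) for c in columns if (m := pat.match(c))]
    return [c for _, c in sorted(hits)]


def read_evidence(path, design: SetDesign, ri_prefix: str = RI_PREFIX) -> PsmTable:
    """Parse an evidence table and map reporter columns onto the design.

    Reporter columns are matched by ordered position within ``ri_prefix``
    against each run's ordered channel list; all runs in one file must share
    the same channel count. MaxQuant encodes below-noise reporter signal as 0;
    zeros are converted to explicit missing values.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for col in REQUIRED_EVIDENCE:
        if col not in df.columns:
            raise FormatError(f"evidence file missing required column {col!r}")

    ri_cols = _reporter_columns(df.columns, ri_prefix)
    if not ri_cols:
        raise FormatError(f"no reporter columns with prefix {ri_prefix!r} found")
    snr_cols = _reporter_columns(df.columns, SNR_PREFIX)

    runs_in_file = df["Raw file"].unique()
    for run_id in runs_in_file:
        if run_id not in design:
            raise DesignError(f"run {run_id!r} in evidence file absent from design")
        labels = design[run_id].labels
        if len(labels) != len(ri_cols):
            raise DesignError(
                f"run {run_id!r}: {len(ri_cols)} reporter columns in file but "
                f"{len(labels)} channels in design"
            )

    out = pd.DataFrame(index=df.index)
    for src, dst in EVIDENCE_COLUMNS.items():
        if src in df.columns:
            out[dst] = df[src]
    if "pep_updated" not in out.columns:
        out["pep_updated"] = out["pep"]
    for col, default in (("pif", np.nan), ("rt", np.nan)):
        if col not in out.columns:
            out[col] = default
    for col in ("is_reverse", "is_contaminant"):
        if col in out.columns:
            out[col] = out[col].isin(["+", True, 1, "1", "True"])
        else:
            out[col] = False

    # channel labels are taken from the first run; the design guarantees all
    # runs in the file have the same plex size
    labels = design[runs_in_file[0]].labels
    for lbl, src in zip(labels, ri_cols):
        vals = pd.to_numeric(df[src], errors="coerce")
        out[f"ri_{lbl}"] = vals.where(vals > 0)  # 0 == below-noise == missing
    for lbl, src in zip(labels, snr_cols):
        vals = pd.to_numeric(df[src], errors="coerce")
        out[f"snr_{lbl}"] = vals.where(vals > 0)

    # reject rows with unparseable required scalar fields
    out["pep"] = pd.to_numeric(out["pep"], errors="coerce")
    out["pep_updated"] = pd.to_numeric(out["pep_updated"], errors="coerce")
    ok = out["sequence"].notna() & out["leading_razor_protein"].notna() & out["pep"].notna()
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("rejected %d evidence rows with unparseable required fields", n_bad)
        out = out[ok]

    return PsmTable(out, labels, design)


def write_evidence(psm: PsmTable, path, sep: str = "\t") -> None:
    """Write a PsmTable back to the evidence dialect (round-trippable)."""
    df = psm.df
    out = pd.DataFrame(index=df.index)
    for src, dst in EVIDENCE_COLUMNS.items():
        if dst in df.columns:
            out[src] = df[dst]
    out["Reverse"] = np.where(df["is_reverse"], "+", "")
    out["Potential contaminant"] = np.where(df["is_contaminant"], "+", "")
    for i, lbl in enumerate(psm.channels):
        out[f"{RI_PREFIX} {i}"] = df[f"ri_{lbl}"].fillna(0.0)
        snr = f"snr_{lbl}"
        if snr in df.columns:
            out[f"{SNR_PREFIX} {i}"] = df[snr].fillna(0.0)
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# design config

def read_design(path) -> SetDesign:
    """Read a channel design from YAML (nested) or CSV (one row per channel)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        runs = []
        for run_id, spec in (cfg.get("runs") or {}).items():
            channels = [
                Channel(
                    label=str(c["label"]),
                    role=c["role"],
                    cell_type=c.get("cell_type"),
                    well_id=c.get("well_id"),
                )
                for c in spec["channels"]
            ]
            batch = spec.get("batch", {})
            runs.append(
                RunDesign(
                    run_id=str(run_id),
                    channels=channels,
                    plate=str(batch.get("plate", "plate1")),
                    tmt_kit=str(batch.get("tmt_kit", "16plex")),
                )
            )
        return SetDesign(runs)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    need = {"run_id", "channel_label", "role"}
    if not need.issubset(df.columns):
        raise FormatError(f"design CSV requires columns {sorted(need)}")
    runs = []
    for run_id, sub in df.groupby("run_id", sort=False):
        channels = [
            Channel(
                label=str(r.channel_label),
                role=r.role,
                cell_type=getattr(r, "cell_type", None) if pd.notna(getattr(r, "cell_type", np.nan)) else None,
                well_id=str(getattr(r, "well_id", "")) or None,
            )
            for r in sub.itertuples()
        ]
        plate = str(sub["plate"].iloc[0]) if "plate" in sub else "plate1"
        kit = str(sub["tmt_kit"].iloc[0]) if "tmt_kit" in sub else "16plex"
        runs.append(RunDesign(str(run_id), channels, plate=plate, tmt_kit=kit))
    return SetDesign(runs)


def write_design(design: SetDesign, path) -> None:
    path = Path(path)
    cfg = {"runs": {}}
    for run in design:
        cfg["runs"][run.run_id] = {
            "batch": {"plate": run.plate, "tmt_kit": run.tmt_kit},
            "channels": [
                {
                    "label": c.label,
                    "role": c.role,
                    **({"cell_type": c.cell_type} if c.cell_type else {}),
                    **({"well_id": c.well_id} if c.well_id else {}),
                }
                for c in run.channels
            ],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# released-data layout

def write_outputs(
    peptide_matrix: QuantMatrix,
    protein_matrix: QuantMatrix,
    cell_meta: pd.DataFrame,
    out_dir,
    peptide_to_protein: pd.Series | None = None,
) -> dict[str, Path]:
    """Write Peptides-raw.csv, Proteins-processed.csv and Cells.csv.

    Only single-cell wells appear as columns. The peptide file's first two
    columns are the protein id and the peptide sequence.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pep_cells = list(peptide_matrix.cell_ids)
    prot_cells = list(protein_matrix.cell_ids)
    if set(prot_cells) - set(pep_cells):
        raise ValueError(
            "cell id mismatch: protein matrix contains cells absent from the peptide matrix"
        )

    pep = peptide_matrix.values.copy()
    pep.insert(
        0,
        "protein",
        peptide_to_protein.reindex(pep.index)
        if peptide_to_protein is not None
        else pd.Series("", index=pep.index),
    )
    pep.index.name = "sequence"
    paths = {}
    paths["peptides"] = out_dir / "Peptides-raw.csv"
    pep.reset_index().set_index("protein").to_csv(paths["peptides"])

    prot = protein_matrix.values.copy()
    prot.index.name = "protein"
    paths["proteins"] = out_dir / "Proteins-processed.csv"
    prot.to_csv(paths["proteins"])

    meta = cell_meta.reindex(prot_cells)
    paths["cells"] = out_dir / "Cells.csv"
    meta.T.to_csv(paths["cells"], index_label="annotation")
    return paths


def read_protein_matrix(path) -> QuantMatrix:
    """Re-read a Proteins-processed.csv written by :func:`write_outputs`."""
    df = pd.read_csv(path, index_col=0)
    return QuantMatrix(df, level="protein", state="batch_corrected")


# ---------------------------------------------------------------------------
# RNA counts and regulons

def read_rna(path, genes_path=None, barcodes_path=None) -> pd.DataFrame:
    """Gene x cell RNA count matrix from MTX (+sidecars) or dense CSV."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        mat = scipy.io.mmread(path)
        mat = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        genes_path = genes_path or path.with_name("genes.txt")
        barcodes_path = barcodes_path or path.with_name("barcodes.txt")
        genes = [l.strip() for l in open(genes_path) if l.strip()]
        cells = [l.strip() for l in open(barcodes_path) if l.strip()]
        return pd.DataFrame(mat, index=genes, columns=cells)
    return pd.read_csv(path, index_col=0)


def write_rna(counts: pd.DataFrame, path) -> None:
    """Write counts as MatrixMarket with genes.txt / barcodes.txt sidecars."""
    path = Path(path)
    scipy.io.mmwrite(path.with_suffix(".mtx"), scipy.sparse.csr_matrix(counts.to_numpy()))
    path.with_name("genes.txt").write_text("\n".join(counts.index) + "\n")
    path.with_name("barcodes.txt").write_text("\n".join(counts.columns) + "\n")


def read_regulon(path) -> RegulonTable:
    return RegulonTable(pd.read_csv(path))


def filter_rna_cells(counts: pd.DataFrame, min_umi: int = 10_000) -> pd.DataFrame:
    """Drop droplets with fewer than ``min_umi`` total UMIs (background)."""
    return counts.loc[:, counts.sum(axis=0) >= min_umi]
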