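"""PSM, peptide and protein filtering with a per-step count ledger.

The chain mirrors the published filtration summary: drop runs with too few
PSMs, filter unique peptides and (best-peptide) proteins to 1% FDR, remove
reverse/contaminant hits, and — in stringent mode — drop low-purity (PIF)
PSMs and peptides whose single-cell signal is implausibly close to the
carrier (ratio filter). FDR is estimated from posterior error probabilities:
the expected FDR of accepting everything up to a PEP threshold is the mean
PEP of the accepted set, and q-values are the running minimum of that
estimate from the most permissive threshold down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import PsmTable, SetDesign

log = logging.getLogger(__name__)


@dataclass
class FilterLedger:
    """Ordered record of {step, runs, cells, proteins, peptides, psms}."""

    rows: list[dict] = field(default_factory=list)

    def append(self, step_name: str, psm: PsmTable) -> None:
        self.rows.append({"step": step_name, **psm.counts()})

    def append_counts(self, step_name: str, counts: dict) -> None:
        """Append a row computed outside a PsmTable (matrix-level steps)."""
        self.rows.append({"step": step_name, **counts})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def is_monotonic(self) -> bool:
        """Counts never increase down the ledger."""
        df = self.to_frame()
        for col in ("runs", "cells", "proteins", "peptides", "psms"):
            if col in df and df[col].diff().dropna().gt(0).any():
                return False
        return True


def pep_to_qvalues(peps) -> np.ndarray:
    """Convert posterior error probabilities to q-values.

    Sorting PEPs ascending, the estimated FDR at the threshold that accepts
    the first j items is the running mean of those PEPs; the q-value of item
    i is the minimum estimated FDR over all thresholds that accept it. Tied
    PEPs receive the q-value of the most permissive threshold containing the
    tie, so equal PEPs map to equal q-values.
    """
    peps = np.asarray(peps, dtype=float)
    if peps.size == 0:
        return peps.copy()
    if np.any((peps < 0) | (peps > 1) | ~np.isfinite(peps)):
        raise ValueError("PEP values must lie in [0, 1]")
    order = np.argsort(peps, kind="stable")
    sorted_peps = peps[order]
    running_mean = np.cumsum(sorted_peps) / np.arange(1, peps.size + 1)
    # ties: every member of a tie gets the estimate at the tie's last index
    last_of_tie = np.searchsorted(sorted_peps, sorted_peps, side="right") - 1
    fdr = running_mean[last_of_tie]
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def filter_runs_min_psms(psm: PsmTable, min_psms: int = 500) -> PsmTable:
    """Remove whole runs with fewer than ``min_psms`` PSMs (failed preps)."""
    counts = psm.df["run_id"].value_counts()
    keep_runs = counts.index[counts >= min_psms]
    return psm.replace(psm.df[psm.df["run_id"].isin(keep_runs)])


def peptide_fdr(psm: PsmTable, alpha: float = 0.01) -> set[str]:
    """Unique peptides passing FDR <= alpha, scored by their best PSM's PEP."""
    if len(psm) == 0:
        return set()
    best = psm.df.groupby("sequence")["pep_updated"].min()
    q = pep_to_qvalues(best.to_numpy())
    return set(best.index[q <= alpha])


def protein_fdr_best_peptide(psm: PsmTable, alpha: float = 0.01) -> set[str]:
    """Proteins passing FDR <= alpha via the best-peptide approach.

    Each protein is represented by its single most confident (minimum
    updated-PEP) peptide; q-values are computed over that reduced set.
    """
    if len(psm) == 0:
        return set()
    best = psm.df.groupby("leading_razor_protein")["pep_updated"].min()
    q = pep_to_qvalues(best.to_numpy())
    return set(best.index[q <= alpha])


def filter_fdr(psm: PsmTable, alpha: float = 0.01) -> PsmTable:
    """Keep PSMs whose peptide AND protein pass the dataset-wide FDR filter."""
    pep_pass = peptide_fdr(psm, alpha)
    prot_pass = protein_fdr_best_peptide(psm, alpha)
    df = psm.df
    keep = df["sequence"].isin(pep_pass) & df["leading_razor_protein"].isin(prot_pass)
    return psm.replace(df[keep])


def remove_reverse_contaminants(psm: PsmTable) -> PsmTable:
    df = psm.df
    return psm.replace(df[~(df["is_reverse"] | df["is_contaminant"])])


def filter_pif(psm: PsmTable, min_pif: float = 0.8) -> PsmTable:
    """Drop PSMs with precursor ion fraction below ``min_pif``.

    Missing PIF is treated as failing: purity cannot be certified.
    """
    pif = psm.df["pif"]
    return psm.replace(psm.df[pif.notna() & (pif >= min_pif)])


def filter_carrier_ratio(
    psm: PsmTable, design: SetDesign, max_ratio: float = 0.1
) -> PsmTable:
    """Drop PSMs whose mean single-cell intensity exceeds ``max_ratio`` x carrier.

    Abnormally high single-cell signal relative to the ~200-cell carrier
    indicates contamination or cross-labeling. The mean is over observed
    single-cell channels only; PSMs with no observed single-cell values are
    retained (ratio undefined), and PSMs with zero/missing carrier intensity
    are removed (logged as carrier_zero).
    """
    df = psm.df
    keep = np.ones(len(df), dtype=bool)
    n_carrier_zero = 0
    for run_id, idx in df.groupby("run_id", sort=False).groups.items():
        run = design[run_id]
        carrier_col = f"ri_{run.by_role('carrier')[0].label}"
        sc_cols = [f"ri_{c.label}" for c in run.by_role("single_cell")]
        sub = df.loc[idx]
        carrier = sub[carrier_col]
        sc_mean = sub[sc_cols].mean(axis=1)  # observed channels only
        bad_carrier = carrier.isna() | (carrier == 0)
        n_carrier_zero += int(bad_carrier.sum())
        ratio = sc_mean / carrier.where(~bad_carrier)
        drop = bad_carrier | (ratio > max_ratio)
        drop &= ~(sc_mean.isna() & ~bad_carrier)  # undefined mean -> keep
        keep[df.index.get_indexer(idx)] = ~drop.to_numpy()
    if n_carrier_zero:
        log.info("carrier_zero: removed %d PSMs with missing/zero carrier", n_carrier_zero)
    return psm.replace(df[keep])


def run_filter_pipeline(
    psm: PsmTable,
    design: SetDesign,
    mode: str = "stringent",
    min_psms: int = 500,
    alpha: float = 0.01,
    min_pif: float = 0.8,
    max_carrier_ratio: float = 0.1,
) -> tuple[PsmTable, FilterLedger]:
    """Apply the filtering chain, recording counts after every step.

    ``fdr1pct`` mode: min-PSM run filter -> peptide+protein FDR -> reverse/
    contaminant removal. ``stringent`` mode additionally applies the PIF and
    carrier-ratio filters. The later cell-QC and min-cell filters operate on
    matrices and extend the ledger downstream.
    """
    if mode not in ("fdr1pct", "stringent"):
        raise ValueError(f"unknown mode {mode!r}")
    ledger = FilterLedger()
    ledger.append("input", psm)
    psm = filter_runs_min_psms(psm, min_psms)
    ledger.append(f"remove runs with < {min_psms} PSMs", psm)
    psm = filter_fdr(psm, alpha)
    ledger.append(f"filter to peptide and protein FDR <= {alpha:g}", psm)
    psm = remove_reverse_contaminants(psm)
    ledger.append("remove reverse and contaminant hits", psm)
    if mode == "stringent":
        psm = filter_pif(psm, min_pif)
        ledger.append(f"remove PSMs with PIF < {min_pif:g}", psm)
        psm = filter_carrier_ratio(psm, design, max_carrier_ratio)
        ledger.append(
            f"remove peptides with single-cell/carrier ratio > {max_carrier_ratio:g}", psm
        )
    return psm, ledger
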