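"""Reporter-ion signal-to-noise to ion-copy conversion and counting error.

On an Orbitrap analyzer, one unit of reporter-ion S/N corresponds to a fixed
number of ions that scales with the square root of the resolving-power
ratio: 3.5 ions per unit S/N at a resolving power of 240,000, hence
3.5 * sqrt(240000 / RP) at resolving power RP (about 6.5 at 70,000). Ion
counts obey Poisson statistics, so the relative sampling (counting) error of
n sampled copies is 1/sqrt(n).

Two conversion modes are exposed. ``continuous`` uses the factor as is;
``reported`` rounds the factor to the nearest integer before multiplying
(6.5 -> 6 at 70,000), which matches the back-of-envelope arithmetic usually
quoted (S/N 50 -> 300 ions). The 6-vs-6.5 discrepancy is inherent to the
published calibration; both behaviors are kept rather than reconciled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import PsmTable, SetDesign

#: ions inducing a unit change in S/N at the calibration resolving power
CALIBRATION_IONS = 3.5
CALIBRATION_RESOLVING_POWER = 240_000


@dataclass
class IonEstimate:
    snr: float
    resolving_power: float
    ions_continuous: float
    ions_reported: float
    sampling_cv: float


def unit_ion_factor(resolving_power: float) -> float:
    """Ions per unit S/N at the given resolving power."""
    if resolving_power <= 0:
        raise ValueError("resolving power must be positive")
    return CALIBRATION_IONS * np.sqrt(CALIBRATION_RESOLVING_POWER / resolving_power)


def snr_to_ions(snr, resolving_power: float, mode: str = "reported"):
    """Convert reporter-ion S/N to ion copies.

    ``mode='continuous'`` multiplies by the exact factor;
    ``mode='reported'`` multiplies by the nearest-integer factor.
    Accepts scalars or arrays; negative S/N is rejected.
    """
    snr_arr = np.asarray(snr, dtype=float)
    if np.any(snr_arr[np.isfinite(snr_arr)] < 0):
        raise ValueError("S/N must be non-negative")
    factor = unit_ion_factor(resolving_power)
    if mode == "reported":
        factor = float(np.rint(factor))
    elif mode != "continuous":
        raise ValueError(f"unknown mode {mode!r}")
    out = snr_arr * factor
    return float(out) if np.isscalar(snr) else out


def sampling_cv(n_ions) -> float:
    """Relative counting error of sampling n ions: sd/mean = 1/sqrt(n)."""
    n = np.asarray(n_ions, dtype=float)
    if np.any(n[np.isfinite(n)] <= 0):
        raise ValueError("ion count must be positive")
    out = 1.0 / np.sqrt(n)
    return float(out) if np.isscalar(n_ions) else out


def estimate(snr: float, resolving_power: float) -> IonEstimate:
    cont = snr_to_ions(snr, resolving_power, "continuous")
    rep = snr_to_ions(snr, resolving_power, "reported")
    return IonEstimate(
        snr=snr,
        resolving_power=resolving_power,
        ions_continuous=cont,
        ions_reported=rep,
        sampling_cv=sampling_cv(cont) if cont > 0 else float("inf"),
    )


def copies_per_gene_summary(
    psm: PsmTable,
    resolving_power: float = 70_000,
    level: str = "protein",
    roles: tuple[str, ...] = ("single_cell",),
) -> pd.DataFrame:
    """Per-gene distribution of ion copies summed over PSMs, per cell.

    For each feature (peptide sequence or leading razor protein), reported-
    mode ion counts of all its PSMs are summed within each cell; the summary
    reports the median and quartiles of the per-cell copy numbers, for
    comparison against an RNA UMI-count distribution.
    """
    if not psm.has_snr:
        raise ValueError("snr_missing: PSM table has no signal-to-noise columns")
    if level not in ("peptide", "protein"):
        raise ValueError(f"unknown level {level!r}")
    key = "sequence" if level == "peptide" else "leading_razor_protein"
    frames = []
    for run_id, sub in psm.df.groupby("run_id", sort=False):
        run = psm.design[run_id]
        chans = [c for c in run.channels if c.role in roles]
        if not chans:
            continue
        snr_cols = [f"snr_{c.label}" for c in chans]
        ions = snr_to_ions(sub[snr_cols].to_numpy(), resolving_power, "reported")
        block = pd.DataFrame(ions, index=sub[key], columns=[
            psm.design.cell_id(run_id, c.label) for c in chans
        ])
        frames.append(block.groupby(level=0).sum(min_count=1))
    per_cell = pd.concat(frames, axis=1)
    stacked = per_cell.stack()
    grouped = stacked.groupby(level=0)
    return pd.DataFrame(
        {
            "median_copies": grouped.median(),
            "q25": grouped.quantile(0.25),
            "q75": grouped.quantile(0.75),
            "n_cells": grouped.size(),
        }
    )
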