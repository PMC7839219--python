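"""Shared data model for the single-cell proteomics pipeline.

The central objects are:

``SetDesign``
    Per-run annotation of TMT channels: which channel carries the isobaric
    carrier (~200 cells), the reference (~5 cells), single cells, control
    wells (no cell, reagents only) or is unused.
``PsmTable``
    Peptide-spectrum matches with identification confidence (PEP, and the
    retention-time-updated PEP), spectral purity (PIF), and per-channel
    reporter-ion intensities / signal-to-noise ratios.
``QuantMatrix``
    A features x cells matrix (peptide- or protein-level) with an explicit
    missing mask (NaN) and a tag recording how far along the normalization
    chain it is.
``RegulonTable``
    Transcription-factor -> target interactions with activation/repression
    sign, in the TRRUST curation schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ROLES = ("carrier", "reference", "unused", "single_cell", "control")

#: Allowed processing states of a QuantMatrix, in pipeline order.
STATES = (
    "raw",
    "reference_normalized",
    "normalized",
    "log2",
    "collapsed",
    "imputed",
    "batch_corrected",
)


class DesignError(ValueError):
    """Channel design inconsistent with itself or with a PSM table."""


class FormatError(ValueError):
    """Input file malformed (missing column, unknown role string, ...)."""


@dataclass(frozen=True)
class Channel:
    """One TMT channel of one run."""

    label: str
    role: str
    cell_type: str | None = None
    well_id: str | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise FormatError(
                f"unknown channel role {self.role!r}; expected one of {ROLES}"
            )


@dataclass
class RunDesign:
    run_id: str
    channels: list[Channel]
    plate: str = "plate1"
    tmt_kit: str = "16plex"

    def __post_init__(self):
        n_carrier = sum(c.role == "carrier" for c in self.channels)
        n_ref = sum(c.role == "reference" for c in self.channels)
        if n_carrier != 1:
            raise DesignError(
                f"run {self.run_id!r} must have exactly one carrier channel, "
                f"found {n_carrier}"
            )
        if n_ref > 1:
            raise DesignError(
                f"run {self.run_id!r} has {n_ref} reference channels (max 1)"
            )
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise DesignError(f"run {self.run_id!r} has duplicate channel labels")

    def by_role(self, *roles: str) -> list[Channel]:
        return [c for c in self.channels if c.role in roles]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]


class SetDesign:
    """Channel design for a collection of multiplexed runs ("sets")."""

    def __init__(self, runs: Iterable[RunDesign]):
        self.runs: dict[str, RunDesign] = {}
        for r in runs:
            if r.run_id in self.runs:
                raise DesignError(f"duplicate run id {r.run_id!r}")
            self.runs[r.run_id] = r
        if not self.runs:
            warnings.warn("empty design: no runs defined", stacklevel=2)

    def __len__(self) -> int:
        return len(self.runs)

    def __contains__(self, run_id: str) -> bool:
        return run_id in self.runs

    def __getitem__(self, run_id: str) -> RunDesign:
        return self.runs[run_id]

    def __iter__(self):
        return iter(self.runs.values())

    def cell_id(self, run_id: str, channel_label: str) -> str:
        """Wells are unique per run x channel."""
        return f"{run_id}:{channel_label}"

    def cells(self, roles: tuple[str, ...] = ("single_cell",)) -> list[str]:
        """Cell ids of all wells with the given roles, in design order."""
        out = []
        for run in self:
            for ch in run.channels:
                if ch.role in roles:
                    out.append(self.cell_id(run.run_id, ch.label))
        return out

    def cell_meta(self) -> pd.DataFrame:
        """Per-well annotation (run, channel, role, type, batch) indexed by cell id."""
        rows = []
        for run in self:
            for ch in run.channels:
                rows.append(
                    {
                        "cell_id": self.cell_id(run.run_id, ch.label),
                        "run_id": run.run_id,
                        "channel": ch.label,
                        "role": ch.role,
                        "cell_type": ch.cell_type,
                        "plate": run.plate,
                        "tmt_kit": run.tmt_kit,
                    }
                )
        return pd.DataFrame(rows).set_index("cell_id")


class PsmTable:
    """Peptide-spectrum-match table with per-channel reporter quantification.

    Backed by a pandas DataFrame. Scalar columns: ``sequence``,
    ``leading_razor_protein``, ``run_id``, ``pep``, ``pep_updated``, ``pif``,
    ``rt``, ``is_reverse``, ``is_contaminant``. Reporter intensities live in
    columns ``ri_<label>`` and signal-to-noise ratios in ``snr_<label>`` for
    each channel label; missing values are NaN.
    """

    SCALAR_COLUMNS = (
        "sequence",
        "leading_razor_protein",
        "run_id",
        "pep",
        "pep_updated",
        "pif",
        "rt",
        "is_reverse",
        "is_contaminant",
    )

    def __init__(self, df: pd.DataFrame, channels: list[str], design: SetDesign):
        missing = [c for c in self.SCALAR_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"PsmTable missing required columns: {missing}")
        for lbl in channels:
            if f"ri_{lbl}" not in df.columns:
                raise FormatError(f"PsmTable missing intensity column ri_{lbl}")
        bad_runs = set(df["run_id"].unique()) - set(design.runs)
        if bad_runs:
            raise DesignError(f"runs present in PSM table but not in design: {sorted(bad_runs)}")
        for col in ("pep", "pep_updated", "pif"):
            v = df[col].to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                if np.any((v < 0) | (v > 1)):
                    raise ValueError(f"{col} values must lie in [0, 1]")
        self.df = df.reset_index(drop=True)
        self.channels = list(channels)
        self.design = design

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ri_columns(self) -> list[str]:
        return [f"ri_{c}" for c in self.channels]

    @property
    def snr_columns(self) -> list[str]:
        return [f"snr_{c}" for c in self.channels]

    @property
    def has_snr(self) -> bool:
        return all(c in self.df.columns for c in self.snr_columns)

    def replace(self, df: pd.DataFrame) -> "PsmTable":
        """New PsmTable with the same channels/design but different rows."""
        return PsmTable(df, self.channels, self.design)

    def counts(self) -> dict[str, int]:
        """Summary counts used by the filter ledger."""
        df = self.df
        runs = df["run_id"].unique()
        n_cells = sum(
            1
            for run in self.design
            if run.run_id in set(runs)
            for ch in run.channels
            if ch.role == "single_cell"
        )
        return {
            "runs": int(len(runs)),
            "cells": int(n_cells),
            "proteins": int(df["leading_razor_protein"].nunique()),
            "peptides": int(df["sequence"].nunique()),
            "psms": int(len(df)),
        }

    def peptide_to_protein(self) -> pd.Series:
        """Map peptide sequence -> leading razor protein (first occurrence wins)."""
        return (
            self.df.groupby("sequence", sort=False)["leading_razor_protein"]
            .first()
        )

    def to_quant_matrix(self, roles: tuple[str, ...] = ("single_cell",)) -> "QuantMatrix":
        """Peptide x cell matrix of reporter intensities for wells of ``roles``.

        Multiple PSMs of the same peptide in one run are aggregated by median.
        """
        frames = []
        for run_id, sub in self.df.groupby("run_id", sort=False):
            run = self.design[run_id]
            chans = [c for c in run.channels if c.role in roles]
            if not chans:
                continue
            block = sub.groupby("sequence")[[f"ri_{c.label}" for c in chans]].median()
            block.columns = [self.design.cell_id(run_id, c.label) for c in chans]
            frames.append(block)
        if not frames:
            values = pd.DataFrame()
        else:
            values = pd.concat(frames, axis=1)
        values.index.name = "sequence"
        return QuantMatrix(values, level="peptide", state="raw")


@dataclass
class QuantMatrix:
    """Features x cells matrix with explicit missingness and a state tag."""

    values: pd.DataFrame
    level: str = "peptide"  # peptide | protein
    state: str = "raw"

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.level not in ("peptide", "protein"):
            raise ValueError(f"unknown level {self.level!r}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value is observed."""
        return self.values.notna()

    def advance(self, values: pd.DataFrame, state: str, level: str | None = None) -> "QuantMatrix":
        """Step to a later pipeline state; enforces forward-only transitions."""
        if STATES.index(state) < STATES.index(self.state):
            raise ValueError(
                f"illegal state transition {self.state!r} -> {state!r}; "
                f"pipeline order is {STATES}"
            )
        return QuantMatrix(values, level=level or self.level, state=state)

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.values.copy(), self.level, self.state)


class RegulonTable:
    """TF -> target interactions with an activation/repression sign."""

    SIGNS = ("activated", "repressed")

    def __init__(self, df: pd.DataFrame):
        need = {"tf", "target", "sign"}
        if not need.issubset(df.columns):
            raise FormatError(f"regulon table requires columns {sorted(need)}")
        bad = set(df["sign"].unique()) - set(self.SIGNS)
        if bad:
            raise FormatError(f"unknown regulon signs {sorted(bad)}; expected {self.SIGNS}")
        if df.duplicated(subset=["tf", "target"]).any():
            raise FormatError("duplicate (tf, target) pairs in regulon table")
        self.df = df.reset_index(drop=True)

    def targets(self, tf: str, sign: str | None = None) -> list[str]:
        sub = self.df[self.df["tf"] == tf]
        if sign is not None:
            sub = sub[sub["sign"] == sign]
        return sub["target"].tolist()

    @property
    def tfs(self) -> list[str]:
        return sorted(self.df["tf"].unique())
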