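"""Seeded synthetic data emulating multiplexed single-cell proteomics runs.

The generator produces evidence-style PSM tables with a ~200-cell isobaric
carrier, a ~5-cell reference, single-cell and control channels per run,
together with paired RNA counts drawn from the same latent cell states, and
records the ground truth (fold changes, polarization axis, couplings) so
every pipeline stage can be tested without external data.

Generative model, per run:

* DDA-style detection — each run observes a top-fraction of peptides drawn
  by abundance-weighted noisy ranking, so different runs quantify different
  peptide subsets (structural missingness).
* Reporter intensity = channel size (carrier 200, reference 5, cell 1) x
  protein abundance x peptide ionization efficiency x log-normal
  multiplicative noise, plus an additive coisolation background that is
  independent between peptides. Control wells receive background only,
  which makes their within-protein peptide variation (CV) high — the basis
  of the CV-based cell QC.
* Ion counts are Poisson at the intended copy number and reported as S/N
  through the inverse resolving-power calibration; a zero ion draw is a
  missing value (below the S/N threshold).
* PEPs come from a two-component mixture (correct ~ Beta(1, 99),
  incorrect ~ Uniform) with truth labels; PIF sits near 1 with a
  contaminated tail; a small fraction of reverse/contaminant rows and of
  carrier-cross-labeled peptides exercise the corresponding filters.

Cell-type differences are log2 fold changes applied half up / half down
around a shared baseline; macrophage-like cells additionally carry a latent
1-D polarization coordinate that moves a subset of proteins, giving the
continuum the spectral ordering should recover. A per-gene modality sign
anti-couples a minority of proteins from the (RNA-side) latent state,
creating the opposite-covariation gene cluster seen in joint analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Channel, PsmTable, RegulonTable, RunDesign, SetDesign
from .ion_stats import unit_ion_factor


def default_design(
    n_runs: int = 20,
    plex: int = 16,
    n_macrophage: int = 10,
    n_monocyte: int = 3,
    n_control: int = 1,
    seed: int = 0,
) -> SetDesign:
    """Carrier + reference + randomized single cells + control wells per run.

    Defaults give a 16-plex layout (10 macrophage-like, 3 monocyte single
    cells, 1 control, 1 unused channel); pass ``plex=11, n_macrophage=5,
    n_monocyte=2`` for the 11-plex layout. The carrier and reference sit in
    the first two channels; cell types, controls and unused wells are
    shuffled over the remaining channels independently per run, emulating
    the randomization of samples over sets (and keeping cell type from
    being confounded with TMT channel).
    """
    n_used = 2 + n_macrophage + n_monocyte + n_control
    if n_used > plex:
        raise ValueError(f"{n_used} channels requested but plex is {plex}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1_000_001]))
    runs = []
    for r in range(n_runs):
        slots = (
            [("single_cell", "macrophage")] * n_macrophage
            + [("single_cell", "monocyte")] * n_monocyte
            + [("control", None)] * n_control
            + [("unused", None)] * (plex - n_used)
        )
        rng.shuffle(slots)
        channels = [Channel("RI1", "carrier"), Channel("RI2", "reference")]
        for i, (role, ctype) in enumerate(slots, start=3):
            channels.append(Channel(f"RI{i}", role, cell_type=ctype))
        runs.append(
            RunDesign(
                run_id=f"run{r + 1:03d}",
                channels=channels,
                plate=f"plate{r // 32 + 1}",
                tmt_kit=f"{plex}plex",
            )
        )
    return SetDesign(runs)


@dataclass
class SynthTruth:
    """Ground truth of a synthetic experiment.

    Per-protein arrays are aligned with ``protein_ids``; per-peptide arrays
    with ``peptide_ids`` (``pep_protein_idx`` maps peptides to proteins).
    ``log2_fc`` is the macrophage-minus-monocyte fold change on the latent
    (RNA-side) scale; the protein-side fold change is ``modality_sign *
    log2_fc`` (sign -1 marks the anti-coupled, cluster-2-like genes).
    """

    seed: int
    protein_ids: list[str]
    base_log2: np.ndarray
    log2_fc: np.ndarray
    grad_coef: np.ndarray
    modality_sign: np.ndarray
    peptide_ids: list[str]
    pep_protein_idx: np.ndarray
    efficiency: np.ndarray
    # study conditions
    carrier_size: float = 200.0
    reference_size: float = 5.0
    noise_sd: float = 0.25  # ln-scale multiplicative MS noise
    background_frac: float = 0.1  # coisolation background vs single-cell signal
    detect_fraction: float = 0.6
    detect_noise: float = 0.5
    frac_incorrect: float = 0.05
    frac_reverse: float = 0.02
    frac_contaminant: float = 0.01
    frac_cross_labeled: float = 0.02
    resolving_power: float = 70_000.0
    rna_copy_ratio: float = 20.0  # protein copies per RNA copy
    rna_theta: float = 2.0  # negative-binomial dispersion
    # filled by simulate_scope2
    cells: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def protein_log2_fc(self) -> np.ndarray:
        """Generating macrophage/monocyte fold change on the protein side."""
        return self.modality_sign * self.log2_fc

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)


def make_truth(
    n_proteins: int = 3000,
    seed: int = 0,
    pep_min: int = 1,
    pep_max: int = 8,
    fc_sd: float = 0.8,
    grad_frac: float = 0.3,
    grad_sd: float = 0.8,
    frac_cluster2: float = 0.15,
    **param_overrides,
) -> SynthTruth:
    """Draw per-protein and per-peptide ground truth."""
    rng = np.random.default_rng(seed)
    protein_ids = [f"G{i:05d}" for i in range(n_proteins)]
    base_log2 = rng.normal(6.0, 1.5, n_proteins)
    log2_fc = rng.normal(0.0, fc_sd, n_proteins)
    grad_coef = np.where(
        rng.random(n_proteins) < grad_frac, rng.normal(0.0, grad_sd, n_proteins), 0.0
    )
    modality_sign = np.where(rng.random(n_proteins) < frac_cluster2, -1.0, 1.0)
    n_pep = rng.integers(pep_min, pep_max + 1, n_proteins)
    pep_protein_idx = np.repeat(np.arange(n_proteins), n_pep)
    peptide_ids = [
        f"{protein_ids[p]}_pep{j + 1}"
        for p, n in zip(range(n_proteins), n_pep)
        for j in range(n)
    ]
    efficiency = rng.lognormal(0.0, 0.7, len(peptide_ids))
    return SynthTruth(
        seed=seed,
        protein_ids=protein_ids,
        base_log2=base_log2,
        log2_fc=log2_fc,
        grad_coef=grad_coef,
        modality_sign=modality_sign,
        peptide_ids=peptide_ids,
        pep_protein_idx=pep_protein_idx,
        efficiency=efficiency,
        **param_overrides,
    )


def _cell_log2_profile(truth: SynthTruth, cell_type: str, g: float) -> np.ndarray:
    """Protein-side log2 abundance profile of one cell."""
    dev = np.where(cell_type == "macrophage", 0.5, -0.5) * truth.log2_fc
    if cell_type == "macrophage":
        dev = dev + truth.grad_coef * g
    return truth.base_log2 + truth.modality_sign * dev


def simulate_scope2(
    design: SetDesign, truth: SynthTruth | None = None, seed: int = 0
) -> tuple[PsmTable, SynthTruth]:
    """Generate a PSM/evidence table for every run of ``design``.

    Returns the table and the (possibly newly drawn) ground truth, whose
    ``cells`` frame records each well's type and latent polarization.
    """
    if truth is None:
        truth = make_truth(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2_000_001]))
    factor = unit_ion_factor(truth.resolving_power)
    pidx = truth.pep_protein_idx
    n_pep_total = len(truth.peptide_ids)
    exp_sc = truth.efficiency * 2.0 ** truth.base_log2[pidx]  # expected 1-cell signal
    bg_scale = truth.background_frac * exp_sc

    cell_rows = []
    frames = []
    for run in design:
        detect_w = exp_sc * rng.lognormal(0.0, truth.detect_noise, n_pep_total)
        n_detect = int(round(truth.detect_fraction * n_pep_total))
        detected = np.sort(np.argsort(detect_w)[::-1][:n_detect])
        d_pidx = pidx[detected]
        d_eff = truth.efficiency[detected]

        values = {}
        carrier_vals = None
        sc_cols = []
        for ch in run.channels:
            if ch.role == "unused":
                continue
            if ch.role == "carrier":
                size, profile = truth.carrier_size, truth.base_log2
            elif ch.role == "reference":
                size, profile = truth.reference_size, truth.base_log2
            elif ch.role == "single_cell":
                g = float(rng.uniform(-1.0, 1.0)) if ch.cell_type == "macrophage" else 0.0
                cell_rows.append(
                    {
                        "cell_id": design.cell_id(run.run_id, ch.label),
                        "run_id": run.run_id,
                        "channel": ch.label,
                        "cell_type": ch.cell_type,
                        "polarization": g,
                    }
                )
                size, profile = 1.0, _cell_log2_profile(truth, ch.cell_type, g)
            else:  # control
                size, profile = 0.0, truth.base_log2
            signal = size * d_eff * 2.0 ** profile[d_pidx]
            signal = signal * rng.lognormal(0.0, truth.noise_sd, n_detect)
            background = rng.exponential(bg_scale[detected])
            v = signal + background
            values[ch.label] = v
            if ch.role == "carrier":
                carrier_vals = v
            elif ch.role in ("single_cell", "control"):
                sc_cols.append(ch.label)

        # carrier cross-labeling: inflate single-cell/control signal for a few peptides
        n_cross = rng.binomial(n_detect, truth.frac_cross_labeled)
        if n_cross and carrier_vals is not None:
            cross = rng.choice(n_detect, n_cross, replace=False)
            for lbl in sc_cols:
                values[lbl][cross] += carrier_vals[cross] * rng.uniform(0.15, 0.4, n_cross)

        df = pd.DataFrame(
            {
                "sequence": [truth.peptide_ids[i] for i in detected],
                "leading_razor_protein": [truth.protein_ids[p] for p in d_pidx],
                "run_id": run.run_id,
            }
        )
        for ch in run.channels:
            if ch.role == "unused":
                df[f"ri_{ch.label}"] = np.nan
                df[f"snr_{ch.label}"] = np.nan
                continue
            ions = rng.poisson(values[ch.label])
            ri = np.where(ions > 0, values[ch.label], np.nan)
            df[f"ri_{ch.label}"] = ri
            df[f"snr_{ch.label}"] = np.where(ions > 0, ions / factor, np.nan)
        frames.append(df)

    df = pd.concat(frames, ignore_index=True)
    n = len(df)

    correct = rng.random(n) >= truth.frac_incorrect
    pep = np.where(correct, rng.beta(1.0, 99.0, n), rng.uniform(0.0, 1.0, n))
    pep_updated = np.clip(np.where(correct, pep * 0.5, pep * 1.5), 0.0, 1.0)
    pif = np.where(
        rng.random(n) < 0.95, rng.beta(18.0, 1.0, n), rng.beta(2.0, 2.0, n)
    )
    pif[rng.random(n) < 0.02] = np.nan
    df["pep"] = pep
    df["pep_updated"] = pep_updated
    df["pif"] = pif
    df["rt"] = rng.uniform(0.0, 60.0, n)
    df["truth_correct"] = correct

    is_rev = rng.random(n) < truth.frac_reverse
    is_con = ~is_rev & (rng.random(n) < truth.frac_contaminant)
    df["is_reverse"] = is_rev
    df["is_contaminant"] = is_con
    df.loc[is_rev, "leading_razor_protein"] = "REV__" + df.loc[is_rev, "leading_razor_protein"]
    df.loc[is_rev, "sequence"] = "REV__" + df.loc[is_rev, "sequence"]
    df.loc[is_rev, ["pep", "pep_updated"]] = rng.uniform(0.1, 1.0, (int(is_rev.sum()), 2))
    df.loc[is_con, "leading_razor_protein"] = "CON__" + df.loc[is_con, "leading_razor_protein"]

    labels = next(iter(design)).labels
    truth.cells = pd.DataFrame(cell_rows).set_index("cell_id") if cell_rows else None
    return PsmTable(df, labels, design), truth


def simulate_rna(
    truth: SynthTruth,
    n_cells: int = 260,
    depth: float = 15_000.0,
    frac_macrophage: float = 0.77,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial RNA counts from the same latent cell states.

    Per-gene means follow the latent (RNA-side) abundances — the modality
    sign is NOT applied, so anti-coupled genes diverge between modalities —
    at roughly 1/``rna_copy_ratio`` of the protein copy scale. Returns the
    gene x cell count matrix and per-cell metadata (type, polarization,
    size factor).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3_000_001]))
    types = np.where(rng.random(n_cells) < frac_macrophage, "macrophage", "monocyte")
    g = np.where(types == "macrophage", rng.uniform(-1.0, 1.0, n_cells), 0.0)
    size_factor = rng.lognormal(0.0, 0.3, n_cells)
    dev = np.where(types == "macrophage", 0.5, -0.5)[None, :] * truth.log2_fc[:, None]
    dev = dev + truth.grad_coef[:, None] * g[None, :]
    log2_mean = truth.base_log2[:, None] + dev  # latent scale, no modality sign
    rel = 2.0 ** log2_mean
    rel = rel / rel.sum(axis=0, keepdims=True)
    mean = rel * depth * size_factor[None, :]
    theta = truth.rna_theta
    counts = rng.negative_binomial(theta, theta / (theta + mean))
    cells = [f"rna_cell{i + 1:04d}" for i in range(n_cells)]
    counts_df = pd.DataFrame(counts, index=truth.protein_ids, columns=cells)
    meta = pd.DataFrame(
        {"cell_type": types, "polarization": g, "size_factor": size_factor},
        index=cells,
    )
    return counts_df, meta


def simulate_joint(
    n_genes: int = 200,
    n_cells: int = 300,
    frac_cluster2: float = 0.3,
    noise: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Paired (normalized) RNA and protein matrices with known gene clusters.

    A shared latent cell state drives every gene; cluster-1 genes load with
    the same sign in both modalities, cluster-2 genes with opposite signs.
    Loadings have magnitude >= 0.5 with balanced random signs, so every gene
    carries recoverable covariation structure. RNA and protein cells are
    distinct draws from the same state distribution.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4_000_001]))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    loading = rng.uniform(0.5, 1.5, n_genes) * rng.choice([-1.0, 1.0], n_genes)
    cluster = np.where(rng.random(n_genes) < frac_cluster2, 2, 1)
    sign = np.where(cluster == 1, 1.0, -1.0)
    s_rna = rng.standard_normal(n_cells)
    s_prot = rng.standard_normal(n_cells)
    rna = loading[:, None] * s_rna[None, :] + noise * rng.standard_normal((n_genes, n_cells))
    prot = (sign * loading)[:, None] * s_prot[None, :] + noise * rng.standard_normal(
        (n_genes, n_cells)
    )
    rna_df = pd.DataFrame(rna, index=genes, columns=[f"r{i}" for i in range(n_cells)])
    prot_df = pd.DataFrame(prot, index=genes, columns=[f"p{i}" for i in range(n_cells)])
    return rna_df, prot_df, pd.Series(cluster, index=genes, name="cluster")


def simulate_tf_regulon(
    n_activated: int = 20,
    n_repressed: int = 20,
    n_cells: int = 500,
    coupling: float = 0.5,
    noise: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, RegulonTable]:
    """An activator TF whose protein couples + to activated, - to repressed targets.

    Returns (rna, prot, pairing, regulons) ready for
    :func:`scope2.joint.tf_target_correlations`; the pairing is the identity
    (the same latent cells observed in both modalities).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5_000_001]))
    activity = rng.standard_normal(n_cells)
    cells = [f"c{i}" for i in range(n_cells)]
    act = [f"ACT{i + 1:03d}" for i in range(n_activated)]
    rep = [f"REP{i + 1:03d}" for i in range(n_repressed)]
    rna_rows = {"TF1": activity + noise * rng.standard_normal(n_cells)}
    for t in act:
        rna_rows[t] = coupling * activity + noise * rng.standard_normal(n_cells)
    for t in rep:
        rna_rows[t] = -coupling * activity + noise * rng.standard_normal(n_cells)
    rna = pd.DataFrame(rna_rows, index=cells).T
    prot = pd.DataFrame(
        {"TF1": activity + 0.25 * noise * rng.standard_normal(n_cells)}, index=cells
    ).T
    pairing = pd.DataFrame(
        {"cell_a": cells, "cell_b": cells, "rank": range(1, n_cells + 1)}
    )
    regulons = RegulonTable(
        pd.DataFrame(
            {
                "tf": "TF1",
                "target": act + rep,
                "sign": ["activated"] * n_activated + ["repressed"] * n_repressed,
            }
        )
    )
    return rna, prot, pairing, regulons
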