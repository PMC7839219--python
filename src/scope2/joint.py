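"""Joint RNA-protein covariation analysis.

For each gene measured in both modalities, the gene's covariation is
summarized by its vector of Pearson correlations to all other shared genes,
computed separately from the RNA and the protein data (r_i and p_i). The
correlation rho_rp between r_i and p_i measures whether the gene covaries
with the rest of the transcriptome and proteome in the same way; its
distribution over genes is typically bimodal, defining a cluster of
concordant genes (positive mode) and a cluster with opposite covariation
(negative mode). Common PCA finds the axis shared by both modalities — the
leading eigenvector of the sum of the two gene-gene correlation matrices —
which orders cells of either modality so that cells in similar states can be
paired by rank. Regulon analysis then correlates transcription-factor
abundance with the RNA of its activated and repressed targets across the
paired cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .data_model import RegulonTable

DEGENERACY_TOL = 1e-9
#: minimum separation of mixture means to call the rho distribution bimodal
MIN_MODE_SEPARATION = 0.15


@dataclass
class CovarPair:
    gene: str
    rho_rp: float
    cluster: int | None = None  # 1 | 2 | None


@dataclass
class CpcResult:
    cpc1: pd.Series  # unit vector over shared genes
    rna_cell_scores: pd.Series
    protein_cell_scores: pd.Series
    rna_ranks: pd.Series
    protein_ranks: pd.Series
    eigenvalues: np.ndarray


def _shared(rna: pd.DataFrame, prot: pd.DataFrame) -> list[str]:
    genes = [g for g in rna.index if g in set(prot.index)]
    if len(genes) < 3:
        raise ValueError("need at least 3 shared genes")
    return genes


def _corr_matrix(df: pd.DataFrame) -> np.ndarray:
    return np.corrcoef(df.to_numpy(dtype=float))


def correlation_vectors(
    rna: pd.DataFrame, prot: pd.DataFrame
) -> tuple[list[CovarPair], np.ndarray, np.ndarray]:
    """rho_rp per shared gene, plus the two gene-gene correlation matrices.

    Self-correlations (identically 1) are excluded from r_i and p_i so they
    cannot inflate the agreement.
    """
    genes = _shared(rna, prot)
    Rr = _corr_matrix(rna.loc[genes])
    Rp = _corr_matrix(prot.loc[genes])
    pairs = [
        CovarPair(gene=g, rho_rp=_rho_excluding_self(Rr, Rp, i))
        for i, g in enumerate(genes)
    ]
    return pairs, Rr, Rp


def _rho_excluding_self(Rr: np.ndarray, Rp: np.ndarray, i: int) -> float:
    mask = np.ones(Rr.shape[0], dtype=bool)
    mask[i] = False
    r_i, p_i = Rr[i, mask], Rp[i, mask]
    if np.std(r_i) == 0 or np.std(p_i) == 0:
        return float("nan")
    return float(np.corrcoef(r_i, p_i)[0, 1])


def permutation_null(
    Rr: np.ndarray, Rp: np.ndarray, n_perm: int, seed: int
) -> np.ndarray:
    """Null rho_rp obtained by permuting the gene alignment between modalities.

    Each permutation relabels the protein genes relative to the RNA genes and
    recomputes rho_rp for every gene; returns the pooled null draws.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    n = Rr.shape[0]
    out = np.empty((n_perm, n))
    for b in range(n_perm):
        perm = rng.permutation(n)
        Rp_perm = Rp[np.ix_(perm, perm)]
        for i in range(n):
            out[b, i] = _rho_excluding_self(Rr, Rp_perm, i)
    return out.ravel()


def define_gene_clusters(pairs: list[CovarPair], posterior_min: float = 0.75) -> list[CovarPair]:
    """Assign genes to the positive (cluster 1) or negative (cluster 2) mode.

    A 2-component Gaussian mixture is fitted to the rho_rp values; genes are
    assigned to the component claiming them with posterior >= 0.75, the
    higher-mean component being cluster 1. If the two modes are not separated
    (mean gap < 0.15) the distribution is treated as unimodal and all genes
    stay unassigned, with a warning.
    """
    rho = np.array([p.rho_rp for p in pairs])
    finite = np.isfinite(rho)
    for p in pairs:
        p.cluster = None
    if finite.sum() < 2:
        warnings.warn("too few genes to define covariation clusters", stacklevel=2)
        return pairs
    gm = GaussianMixture(n_components=2, random_state=0, n_init=5)
    gm.fit(rho[finite, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    # Ashman's D: mode separation in units of within-mode spread; a single
    # Gaussian split in two lands near D ~ 2, true modes land much higher
    ashman_d = abs(means[0] - means[1]) / np.sqrt((sds**2).sum() / 2)
    if abs(means[0] - means[1]) < MIN_MODE_SEPARATION or ashman_d < 3.0:
        warnings.warn(
            "rho_rp distribution not bimodal; no covariation clusters assigned",
            stacklevel=2,
        )
        return pairs
    hi = int(np.argmax(means))  # cluster 1 = positive mode
    post = gm.predict_proba(rho[finite, None])
    assigned = np.full(finite.sum(), None, dtype=object)
    conf = post.max(axis=1) >= posterior_min
    comp = post.argmax(axis=1)
    assigned[conf & (comp == hi)] = 1
    assigned[conf & (comp != hi)] = 2
    j = 0
    for i, p in enumerate(pairs):
        if finite[i]:
            p.cluster = assigned[j]
            j += 1
    return pairs


def cpca(Rr: np.ndarray, Rp: np.ndarray, rna: pd.DataFrame, prot: pd.DataFrame) -> CpcResult:
    """Common PCA: leading unit eigenvector of Rr + Rp, plus cell scores.

    Cell scores are each modality's gene x cell matrix projected onto the
    common axis; ranks are ordinal. The axis orientation is fixed so that it
    correlates positively with the protein modality's own PC1. A degenerate
    leading eigenvalue (gap below tolerance) is an error, because the common
    axis is then not identifiable.
    """
    genes = [g for g in rna.index if g in set(prot.index)]
    if len(genes) < 2:
        raise ValueError("need at least 2 shared genes")
    S = np.asarray(Rr) + np.asarray(Rp)
    if S.shape != (len(genes), len(genes)):
        raise ValueError("correlation matrices do not match the shared gene space")
    evals, evecs = np.linalg.eigh(S)
    if abs(evals[-1] - evals[-2]) < DEGENERACY_TOL:
        raise ValueError("degenerate_cpc: leading eigenvalue is not unique")
    cpc1 = evecs[:, -1]
    # orientation: positive correlation with the protein PC1
    p_evals, p_evecs = np.linalg.eigh(np.asarray(Rp))
    pc1_prot = p_evecs[:, -1]
    if np.dot(cpc1, pc1_prot) < 0:
        cpc1 = -cpc1
    cpc1 = pd.Series(cpc1, index=genes, name="CPC1")
    rna_scores = rna.loc[genes].T @ cpc1
    prot_scores = prot.loc[genes].T @ cpc1
    return CpcResult(
        cpc1=cpc1,
        rna_cell_scores=rna_scores,
        protein_cell_scores=prot_scores,
        rna_ranks=rna_scores.rank(method="first"),
        protein_ranks=prot_scores.rank(method="first"),
        eigenvalues=evals[::-1],
    )


def pair_cells_by_rank(scores_a: pd.Series, scores_b: pd.Series) -> pd.DataFrame:
    """Pair the i-th ranked cell of modality A with the i-th ranked of B.

    Requires equal cell numbers (subsample the larger set first). If the two
    score vectors anti-align (negative Pearson correlation entrywise), B's
    axis is flipped before ranking so both axes point the same way. Ties are
    broken by stable cell-id order.
    """
    if len(scores_a) != len(scores_b):
        raise ValueError(
            "modalities have different cell counts; subsample the larger set first"
        )
    a = scores_a.sort_index()
    b = scores_b.sort_index()
    if len(a) > 1:
        r = np.corrcoef(a.to_numpy(dtype=float), b.to_numpy(dtype=float))[0, 1]
        if np.isfinite(r) and r < 0:
            b = -b
    order_a = a.sort_values(kind="stable").index
    order_b = b.sort_values(kind="stable").index
    return pd.DataFrame({"cell_a": order_a, "cell_b": order_b, "rank": range(1, len(a) + 1)})


def tf_target_correlations(
    rna: pd.DataFrame,
    prot: pd.DataFrame,
    pairing: pd.DataFrame,
    regulons: RegulonTable,
    min_targets: int = 3,
) -> pd.DataFrame:
    """Correlate TF abundance with its targets' RNA across rank-paired cells.

    For every TF present in the regulon table, the TF's abundance (protein
    and, separately, RNA) is correlated with each target gene's RNA level
    across the paired cells, targets are split into activated vs repressed,
    and a two-sided Mann-Whitney test compares the two correlation
    distributions. TFs with fewer than ``min_targets`` quantified targets on
    either side are reported as underpowered (no p-value).
    """
    rna_cells = pairing["cell_a"].tolist()
    prot_cells = pairing["cell_b"].tolist()
    rows = []
    for tf in regulons.tfs:
        act = [t for t in regulons.targets(tf, "activated") if t in rna.index]
        rep = [t for t in regulons.targets(tf, "repressed") if t in rna.index]
        target_rna = rna.loc[act + rep, rna_cells].to_numpy(dtype=float)
        for modality, source in (("protein", prot), ("rna", rna)):
            if tf not in source.index:
                continue
            cells = prot_cells if modality == "protein" else rna_cells
            tf_vals = source.loc[tf, cells].to_numpy(dtype=float)
            if np.std(tf_vals) == 0:
                continue
            cors = np.array(
                [
                    np.corrcoef(tf_vals, target_rna[i])[0, 1]
                    if np.std(target_rna[i]) > 0
                    else np.nan
                    for i in range(len(act) + len(rep))
                ]
            )
            c_act = cors[: len(act)]
            c_rep = cors[len(act):]
            c_act, c_rep = c_act[np.isfinite(c_act)], c_rep[np.isfinite(c_rep)]
            underpowered = len(c_act) < min_targets or len(c_rep) < min_targets
            if underpowered:
                u = p = np.nan
            else:
                u, p = stats.mannwhitneyu(c_act, c_rep, alternative="two-sided")
            rows.append(
                {
                    "tf": tf,
                    "tf_modality": modality,
                    "n_activated": len(c_act),
                    "n_repressed": len(c_rep),
                    "median_r_activated": float(np.median(c_act)) if len(c_act) else np.nan,
                    "median_r_repressed": float(np.median(c_rep)) if len(c_rep) else np.nan,
                    "statistic": u,
                    "p": p,
                    "underpowered": underpowered,
                }
            )
    return pd.DataFrame(rows)
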