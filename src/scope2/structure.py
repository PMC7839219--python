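"""Population-structure analysis: weighted PCA, spectral (Fiedler) ordering,
variable-protein selection, bulk marker derivation and gene-set enrichment.

Weighted PCA upweights proteins that covary with many others: each protein's
weight is the dot product of its vector of Pearson correlations to all
proteins with itself, and PCA is performed on the cell-cell correlation
matrix of the weighted data. Spectral ordering connects cells in a graph
with weights w_ij = Pearson(cell_i, cell_j) + 1 (all positive) and sorts
cells by the Fiedler vector — the unit eigenvector of the graph Laplacian
L = D - W with the second-smallest eigenvalue, which minimizes
v'Lv = 1/2 * sum_ij w_ij (v_i - v_j)^2 subject to v'v = 1 and orthogonality
to the constant vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import QuantMatrix

#: eigenvalue gap below which multiplicity is declared
DEGENERACY_TOL = 1e-9


@dataclass
class PcaResult:
    cell_scores: pd.DataFrame  # cells x components
    variance_fraction: np.ndarray
    protein_weights: pd.Series


@dataclass
class SpectralResult:
    weights: pd.DataFrame  # cell x cell, Pearson + 1
    eigenvalues: np.ndarray  # ascending
    fiedler: pd.Series  # unit norm, sign fixed
    ordering: list[str]  # cell ids sorted by fiedler entry
    degenerate: bool = False


def _dense(values: pd.DataFrame) -> np.ndarray:
    """Matrix with residual missing entries replaced by the feature mean.

    Imputation can leave a few entries missing (no neighbor observed the
    feature); correlations need complete data, and the feature mean is the
    neutral fill on the centered, normalized scale.
    """
    X = values.to_numpy(dtype=float)
    if np.isnan(X).any():
        row_mean = np.nanmean(X, axis=1)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = np.take(np.nan_to_num(row_mean), idx[0])
    return X


def weighted_pca(m: QuantMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of the cell-cell correlation matrix of covariation-weighted data.

    Zero-variance proteins (undefined correlations) are dropped with a
    warning. Component scores are the eigenvectors of the cell correlation
    matrix; variance fractions are eigenvalues over the trace.
    """
    values = m.values
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance proteins before weighted PCA",
            stacklevel=2,
        )
        values = values[keep]
    X = _dense(values)
    corr = np.corrcoef(X)  # protein x protein, includes self-correlation
    w = np.einsum("ij,ij->i", corr, corr)  # r_i . r_i
    Xw = X * w[:, None]
    cell_corr = np.corrcoef(Xw.T)
    evals, evecs = np.linalg.eigh(cell_corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # deterministic sign: largest-|entry| coordinate positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1
    k = n_components or len(evals)
    scores = pd.DataFrame(
        evecs[:, :k],
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(
        cell_scores=scores,
        variance_fraction=evals[:k] / evals.sum(),
        protein_weights=pd.Series(w, index=values.index),
    )


def cell_graph_weights(m: QuantMatrix, cells: list[str] | None = None) -> pd.DataFrame:
    """Cell-cell weight matrix W = Pearson correlation + 1 (entries in [0, 2])."""
    values = m.values if cells is None else m.values[list(cells)]
    W = np.corrcoef(_dense(values).T) + 1.0
    np.fill_diagonal(W, 2.0)
    return pd.DataFrame(W, index=values.columns, columns=values.columns)


def laplacian(W: np.ndarray) -> np.ndarray:
    """Graph Laplacian L = D - W with D the diagonal of row sums."""
    return np.diag(W.sum(axis=1)) - W


def fiedler_order(m: QuantMatrix, cells: list[str] | None = None) -> SpectralResult:
    """Sort cells by the Fiedler vector of their correlation graph.

    The eigenvector sign is fixed by requiring the entry of the first cell
    (in id order) to be non-negative. If the second-smallest eigenvalue is
    degenerate (gap below 1e-9), the ordering falls back to deterministic
    cell-id order with a warning.
    """
    Wdf = cell_graph_weights(m, cells)
    if Wdf.shape[0] < 3:
        raise ValueError("spectral ordering requires at least 3 cells")
    W = Wdf.to_numpy()
    L = laplacian(W)
    evals, evecs = np.linalg.eigh(L)
    v = evecs[:, 1] / np.linalg.norm(evecs[:, 1])
    degenerate = abs(evals[2] - evals[1]) < DEGENERACY_TOL
    cell_ids = list(Wdf.columns)
    first = cell_ids.index(min(cell_ids))
    if v[first] < 0:
        v = -v
    fiedler = pd.Series(v, index=cell_ids)
    if degenerate:
        warnings.warn(
            "degenerate Fiedler eigenvalue; falling back to cell-id order",
            stacklevel=2,
        )
        ordering = sorted(cell_ids)
    else:
        ordering = [cell_ids[i] for i in np.argsort(v, kind="stable")]
    return SpectralResult(
        weights=Wdf,
        eigenvalues=evals,
        fiedler=fiedler,
        ordering=ordering,
        degenerate=degenerate,
    )


def spectral_clusters(res: SpectralResult) -> pd.Series:
    """Two-way split of cells by the sign of their Fiedler entries."""
    return pd.Series(
        np.where(res.fiedler.to_numpy() >= 0, 1, 2), index=res.fiedler.index
    )


def top_variable_proteins(
    m: QuantMatrix,
    grouping,
    fraction: float,
    mode: str = "clusters",
    n_edge: int = 40,
) -> list[str]:
    """Proteins with the largest mean difference between two cell groups.

    ``clusters`` mode: ``grouping`` is a cell -> {1, 2} labelling; proteins
    are ranked by |mean difference| between the clusters. ``edges`` mode:
    ``grouping`` is an ordered cell list; rank by |mean of first n_edge -
    mean of last n_edge| ordered cells. The top ``fraction`` is returned.
    """
    values = m.values
    if mode == "clusters":
        grouping = pd.Series(grouping)
        a = values[grouping.index[grouping == 1]].mean(axis=1)
        b = values[grouping.index[grouping == 2]].mean(axis=1)
    elif mode == "edges":
        ordered = list(grouping)
        a = values[ordered[:n_edge]].mean(axis=1)
        b = values[ordered[-n_edge:]].mean(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    delta = (a - b).abs().sort_values(ascending=False)
    n = max(1, int(round(fraction * len(delta)))) if fraction < 1 else len(delta)
    return delta.index[:n].tolist()


def bulk_markers(
    bulk: QuantMatrix,
    labels: pd.Series,
    n_per_side: int = 30,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Differential proteins between two bulk groups by two-sided t test.

    Welch's (unequal-variance) test per protein; fold change is the
    difference of group means. Among proteins with p < p_max, the
    ``n_per_side`` largest positive and largest negative fold changes are
    selected (fewer if fewer qualify, with a warning).
    """
    labels = pd.Series(labels)
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError("bulk_markers requires exactly two groups")
    cols_a = labels.index[labels == groups[0]]
    cols_b = labels.index[labels == groups[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    A = bulk.values[cols_a].to_numpy(dtype=float)
    B = bulk.values[cols_b].to_numpy(dtype=float)
    t, p = stats.ttest_ind(A, B, axis=1, equal_var=False, nan_policy="omit")
    fc = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
    res = pd.DataFrame(
        {"fold_change": fc, "t": t, "p": p}, index=bulk.values.index
    ).dropna(subset=["p"])
    qual = res[res["p"] < p_max]
    up = qual[qual["fold_change"] > 0].nlargest(n_per_side, "fold_change")
    down = qual[qual["fold_change"] < 0].nsmallest(n_per_side, "fold_change")
    if len(up) < n_per_side or len(down) < n_per_side:
        warnings.warn(
            f"only {len(up)} up / {len(down)} down markers pass p < {p_max}",
            stacklevel=2,
        )
    out = pd.concat([up, down])
    out["direction"] = np.where(out["fold_change"] > 0, str(groups[0]), str(groups[1]))
    return out


def gene_set_enrichment(values: pd.Series, sets: dict[str, list[str]]) -> pd.DataFrame:
    """Distribution-shift enrichment of gene sets against the background.

    For each set, a two-sample Kolmogorov-Smirnov test compares the
    abundances of the set's members with those of all genes; the effect size
    is the mean abundance of the set. p-values are Benjamini-Hochberg
    adjusted across sets. Empty (or absent-from-background) sets are skipped
    with a warning.
    """
    values = values.dropna()
    rows = []
    for name, members in sets.items():
        present = [g for g in members if g in values.index]
        if not present:
            warnings.warn(f"gene set {name!r} has no members present; skipped", stacklevel=2)
            continue
        sub = values.loc[present]
        if set(present) == set(values.index):
            p = 1.0  # identical distributions by construction
            ks = 0.0
        else:
            ks, p = stats.ks_2samp(sub.to_numpy(), values.to_numpy())
        rows.append({"set": name, "n": len(present), "ks": ks, "p": p, "effect": sub.mean()})
    res = pd.DataFrame(rows)
    if len(res):
        res["p_adj"] = multipletests(res["p"], method="fdr_bh")[1]
        res = res.set_index("set")
    return res
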