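"""Reference-similarity embedding and gene-set activity scoring.

Three per-cell summaries used throughout the screen analysis:

* the reference similarity spectrum (RSS): per cell, correlation to each
  reference cluster profile, z-scored within the cell — an integration-robust
  embedding;
* AUCell-style regulon activity: area under the recovery curve of a gene set
  within the top fraction of a cell's expression-ranked genes;
* binned-control module scores: mean expression of a gene set minus the mean
  of expression-matched control genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .io import lognorm_matrix

logger = logging.getLogger("morphoscreen")

RegulonCollection = dict[str, list[str]]


@dataclass
class ReferenceProfiles:
    """Cluster-averaged expression profiles used as an RSS reference."""

    matrix: pd.DataFrame  # region x gene mean log-normalized expression
    counts: pd.DataFrame | None = None  # region x gene aggregated raw sums
    ap_ordinal: pd.Series | None = None
    dorsal: pd.Series | None = None

    @property
    def regions(self) -> list[str]:
        return list(self.matrix.index)


def pseudobulk_reference(adata: ad.AnnData, labels) -> ReferenceProfiles:
    """Per-label mean log-normalized expression plus raw-count sums.

    ``labels`` is a per-cell label vector or the name of an ``obs`` column.
    Labels with zero cells are dropped with a warning.
    """
    if isinstance(labels, str):
        labels = adata.obs[labels]
    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    L = lognorm_matrix(adata)
    X = sp.csr_matrix(adata.X)
    means, sums, kept = [], [], []
    for lab, idx in labels.groupby(labels).groups.items():
        pos = labels.index.get_indexer(idx)
        if len(pos) == 0:
            logger.warning("label %r has no cells; dropped", lab)
            continue
        means.append(np.asarray(L[pos].mean(axis=0)).ravel())
        sums.append(np.asarray(X[pos].sum(axis=0)).ravel())
        kept.append(lab)
    return ReferenceProfiles(
        matrix=pd.DataFrame(means, index=kept, columns=adata.var_names),
        counts=pd.DataFrame(sums, index=kept, columns=adata.var_names),
    )


def _standardize_rows(R: np.ndarray) -> np.ndarray:
    R = R - R.mean(axis=1, keepdims=True)
    sd = R.std(axis=1, keepdims=True)
    out = np.divide(R, sd, out=np.zeros_like(R), where=sd > 0)
    return out


def rss_embed(
    adata: ad.AnnData,
    ref: ReferenceProfiles,
    method: str = "spearman",
) -> pd.DataFrame:
    """Reference similarity spectrum: cell x region correlation z-scores.

    Each cell is correlated (Spearman by default, Pearson optionally) with
    every reference profile over the shared genes, then the correlation vector
    is z-scored within the cell across references. Constant cells get a row of
    zeros with a warning. Being rank-based, the Spearman RSS is invariant to
    monotone per-gene transformations of cell expression.
    """
    shared = [g for g in ref.matrix.columns if g in set(adata.var_names)]
    if len(ref.matrix) < 2:
        raise ValueError("need at least 2 reference regions")
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need >= 10")
    L = lognorm_matrix(adata)
    col_idx = adata.var_names.get_indexer(shared)
    X = np.asarray(L[:, col_idx].todense())
    P = ref.matrix[shared].values

    if method == "spearman":
        Xr = rankdata(X, axis=1)
        Pr = rankdata(P, axis=1)
    elif method == "pearson":
        Xr, Pr = X, P
    else:
        raise ValueError(f"unknown method {method!r}")

    const = X.std(axis=1) == 0
    if const.any():
        logger.warning("%d constant cells get zero RSS rows", int(const.sum()))
    Xs = _standardize_rows(Xr)
    Ps = _standardize_rows(Pr)
    corr = Xs @ Ps.T / Xr.shape[1]
    rss = _standardize_rows(corr)
    rss[const] = 0.0
    return pd.DataFrame(rss, index=adata.obs_names, columns=ref.matrix.index)


def aucell_scores(
    adata: ad.AnnData,
    regulons: RegulonCollection,
    top_fraction: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """AUCell-style activity: per cell, AUC of each gene set's recovery curve.

    Genes are ranked per cell by expression (descending); the recovery curve
    counts set genes among the top ``ceil(top_fraction * n_genes)`` ranks and
    the area under it is normalized so a set occupying the very top ranks
    scores exactly 1. Ties are broken deterministically by higher mean
    expression across cells, then gene id; pass a ``seed`` to randomize the
    tie-break instead. Scores are invariant to rescaling a cell's expression
    by any positive constant. Regulons with no genes in the universe give an
    all-NaN column with a warning.
    """
    X = np.asarray(sp.csr_matrix(adata.X).todense(), dtype=np.float64)
    n_cells, n_genes = X.shape
    threshold = int(np.ceil(top_fraction * n_genes))
    if threshold < 1:
        raise ValueError("top_fraction too small for the gene universe")

    if seed is None:
        mean_expr = X.mean(axis=0)
        tie_key = rankdata(-mean_expr, method="ordinal")  # smaller = stronger
    else:
        tie_key = np.random.default_rng(seed).permutation(n_genes)
    # per-cell rank (1 = highest expression), ties resolved by tie_key
    order = np.lexsort((np.tile(tie_key, (n_cells, 1)), -X), axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(n_cells)[:, None]
    ranks[rows, order] = np.arange(1, n_genes + 1)[None, :]

    gene_pos = {g: i for i, g in enumerate(adata.var_names)}
    out = {}
    for name, genes in regulons.items():
        idx = np.array([gene_pos[g] for g in genes if g in gene_pos], dtype=int)
        if idx.size == 0:
            logger.warning("regulon %r has no genes in the universe", name)
            out[name] = np.full(n_cells, np.nan)
            continue
        r = ranks[:, idx]
        # AUC of step recovery curve = sum over set ranks within threshold
        auc = np.where(r <= threshold, threshold - r + 1, 0).sum(axis=1)
        k = idx.size
        kk = min(k, threshold)
        max_auc = kk * threshold - (kk * (kk - 1)) // 2
        out[name] = auc / max_auc
    return pd.DataFrame(out, index=adata.obs_names)


def module_score(
    adata: ad.AnnData,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-matched gene-module score per cell.

    Mean log-normalized expression of the gene set minus the mean of control
    genes: for every set gene, ``n_ctrl`` controls are drawn (with
    replacement) from the same average-expression bin, where bins are
    ``n_bins`` equal-frequency bins of per-gene mean expression.
    """
    universe = set(adata.var_names)
    genes = [g for g in gene_set if g in universe]
    if not genes:
        raise ValueError("gene_set is empty after intersecting the gene universe")
    L = lognorm_matrix(adata)
    mean_expr = np.asarray(L.mean(axis=0)).ravel()
    n_genes = L.shape[1]
    # equal-frequency bins of mean expression
    order = np.argsort(mean_expr, kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, min(n_bins, n_genes))):
        bin_of[chunk] = b
    bins = {b: np.flatnonzero(bin_of == b) for b in np.unique(bin_of)}

    rng = np.random.default_rng(seed)
    set_idx = adata.var_names.get_indexer(genes)
    ctrl_idx = np.concatenate(
        [rng.choice(bins[bin_of[i]], size=n_ctrl, replace=True) for i in set_idx]
    )
    set_mean = np.asarray(L[:, set_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(L[:, ctrl_idx].mean(axis=1)).ravel()
    return pd.Series(set_mean - ctrl_mean, index=adata.obs_names)


def read_gmt(path: str | Path) -> RegulonCollection:
    """Read TF -> target gene sets from a GMT file."""
    regulons: RegulonCollection = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                regulons[parts[0]] = [g for g in parts[2:] if g]
    return regulons


def write_gmt(regulons: RegulonCollection, path: str | Path, description: str = ".") -> None:
    """Write TF -> target gene sets as GMT."""
    with open(path, "w") as fh:
        for name, genes in regulons.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
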