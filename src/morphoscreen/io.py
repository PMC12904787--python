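"""Readers/writers, QC and normalization for screen experiments.

A screen experiment is held in an :class:`anndata.AnnData`: raw UMI counts in
``.X`` (sparse, integer), per-cell metadata in ``.obs`` (condition, morphogen
doses, line, batch, induction, cluster label once assigned), gene metadata in
``.var`` (including a boolean ``mito`` flag), and the log-normalized layer in
``.layers["lognorm"]`` once computed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("morphoscreen")

SCALE_FACTOR = 10_000.0


def make_screen(
    counts,
    cell_meta: pd.DataFrame,
    gene_meta: pd.DataFrame | None = None,
) -> ad.AnnData:
    """Assemble an AnnData screen experiment from counts and metadata.

    ``counts`` is cell x gene, non-negative integers (dense or sparse).
    ``cell_meta`` must be indexed by cell id in the same order as the rows of
    ``counts``. If ``gene_meta`` is omitted, gene ids are taken from the
    columns of a DataFrame ``counts`` and the ``mito`` flag is inferred from a
    ``MT-`` prefix.
    """
    if isinstance(counts, pd.DataFrame):
        if gene_meta is None:
            gene_meta = pd.DataFrame(index=counts.columns)
        counts = counts.values
    X = sp.csr_matrix(counts)
    if (X.data < 0).any():
        raise ValueError("counts must be non-negative")
    if gene_meta is None:
        gene_meta = pd.DataFrame(index=[f"g{i}" for i in range(X.shape[1])])
    gene_meta = gene_meta.copy()
    if "mito" not in gene_meta.columns:
        gene_meta["mito"] = [str(g).startswith("MT-") for g in gene_meta.index]
    adata = ad.AnnData(X=X, obs=cell_meta.copy(), var=gene_meta)
    return adata


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 1000,
    max_mito_frac: float = 0.10,
    umi_bounds: tuple[int, int] | None = None,
) -> ad.AnnData:
    """Remove low-quality cells.

    Retains cells with at least ``min_genes`` detected (nonzero) genes and a
    mitochondrial UMI fraction strictly below ``max_mito_frac``. If
    ``umi_bounds = (lo, hi)`` is given, total UMI must additionally satisfy
    ``lo < total < hi`` (exclusive bounds). Cell order is preserved.
    """
    X = sp.csr_matrix(adata.X)
    n_detected = X.getnnz(axis=1)
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito = np.asarray(adata.var["mito"], dtype=bool)
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)
    keep = (n_detected >= min_genes) & (mito_frac < max_mito_frac)
    if umi_bounds is not None:
        lo, hi = umi_bounds
        keep &= (totals > lo) & (totals < hi)
    if not keep.any():
        logger.warning("qc_filter removed every cell")
    return adata[keep].copy()


def lognormalize(adata: ad.AnnData, scale_factor: float = SCALE_FACTOR) -> ad.AnnData:
    """Add a ``lognorm`` layer: ln(1 + scale_factor * count / cell_total).

    Counts are left untouched. A cell with zero total counts cannot be
    normalized and raises an error naming the cell.
    """
    X = sp.csr_matrix(adata.X).astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = adata.obs_names[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts; cannot normalize")
    scaled = sp.diags(scale_factor / totals) @ X
    scaled.data = np.log1p(scaled.data)
    out = adata.copy()
    out.layers["lognorm"] = scaled.tocsr()
    return out


def lognorm_matrix(adata: ad.AnnData) -> sp.csr_matrix:
    """Return the lognorm layer, computing it on the fly if absent."""
    if "lognorm" in adata.layers:
        return sp.csr_matrix(adata.layers["lognorm"])
    return sp.csr_matrix(lognormalize(adata).layers["lognorm"])


def write_screen(adata: ad.AnnData, path: str | Path) -> None:
    """Write counts as Matrix Market plus TSV cell/gene metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "counts.mtx"), sp.coo_matrix(adata.X))
    adata.obs.to_csv(path / "cells.tsv", sep="\t", index_label="cell_id")
    adata.var.to_csv(path / "genes.tsv", sep="\t", index_label="gene_id")


def read_screen(path: str | Path) -> ad.AnnData:
    """Read a screen written by :func:`write_screen`."""
    path = Path(path)
    X = sp.csr_matrix(scipy.io.mmread(str(path / "counts.mtx")))
    obs = pd.read_csv(path / "cells.tsv", sep="\t", index_col="cell_id")
    var = pd.read_csv(path / "genes.tsv", sep="\t", index_col="gene_id")
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    obs.index.name = None
    var.index.name = None
    return ad.AnnData(X=X, obs=obs, var=var)


def load_config(path: str | Path) -> dict:
    """Load a nested key-value configuration file (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
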