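"""Dorsoventral and anteroposterior axis scoring.

Forebrain DV scoring grows dorsal and ventral gene modules from literature
seed markers via a gene-gene nearest-neighbor graph, scores cells with
expression-matched module scores, and takes the dorsal minus ventral
difference as the DV/forebrain-axis score. AP/DV model scoring trains
regularized linear models on a labeled reference: an elastic-net regression of
the region ordinal (1 telencephalon, 2 diencephalon, 3 mesencephalon,
4 rhombencephalon) on a latent representation, after a Jaccard-weighted
k-nearest-neighbor label smoothening; and a penalized logistic classifier of
dorsal vs ventral cells whose link-scale output is the DV score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import ElasticNetCV, LogisticRegression
from sklearn.neighbors import NearestNeighbors
from sklearn.decomposition import PCA

from .scoring import module_score

logger = logging.getLogger("morphoscreen")

AP_REGIONS = ["telencephalon", "diencephalon", "mesencephalon", "rhombencephalon"]
AP_ORDINAL = {r: i + 1 for i, r in enumerate(AP_REGIONS)}

#: dorsal and ventral organizer markers (forebrain)
DORSAL_SEEDS = ["PAX6", "GLI3", "BARHL1", "GAS1", "EMX1", "WNT2B"]
VENTRAL_SEEDS = ["NKX2-1", "NKX2-2", "SIX6", "SIX3", "SHH", "RAX", "DLK1", "FOXA2", "SPON1", "SULF1"]


@dataclass
class SeedMarkerSets:
    """Disjoint dorsal/ventral seed marker gene sets."""

    dorsal: list[str] = field(default_factory=lambda: list(DORSAL_SEEDS))
    ventral: list[str] = field(default_factory=lambda: list(VENTRAL_SEEDS))

    def __post_init__(self) -> None:
        if set(self.dorsal) & set(self.ventral):
            raise ValueError("dorsal and ventral seed sets must be disjoint")


def seeded_gene_modules(
    expr: pd.DataFrame,
    seeds: SeedMarkerSets,
    k_neighbors: int = 10,
    n_pcs: int = 20,
) -> tuple[list[str], list[str]]:
    """Grow dorsal/ventral gene modules from seed markers.

    ``expr`` is cells x genes (log-normalized), restricted to the relevant
    progenitor subset and to seeds plus variable genes. Genes are treated as
    observations: each gene vector is standardized across cells, reduced by
    PCA, and a symmetrized k-nearest-neighbor gene graph is built. Genes
    adjacent to a dorsal seed join the dorsal module (likewise ventral); a
    gene adjacent to both sides goes to the side with more seed neighbors
    (dropped on a tie). Seeds always belong to their own module.
    """
    genes = list(expr.columns)
    dorsal_seeds = [g for g in seeds.dorsal if g in genes]
    ventral_seeds = [g for g in seeds.ventral if g in genes]
    for missing in set(seeds.dorsal) - set(dorsal_seeds) | set(seeds.ventral) - set(ventral_seeds):
        logger.warning("seed gene %s absent from the universe; dropped", missing)
    if not dorsal_seeds or not ventral_seeds:
        raise ValueError("all seeds of one side are absent from the gene universe")

    G = expr.values.T.astype(float)  # genes x cells
    sd = G.std(axis=1, keepdims=True)
    G = (G - G.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    n_comp = min(n_pcs, G.shape[0] - 1, G.shape[1] - 1)
    coords = PCA(n_components=n_comp, svd_solver="full").fit_transform(G)

    k = min(k_neighbors, len(genes) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    adj = np.zeros((len(genes), len(genes)), dtype=bool)
    rows = np.repeat(np.arange(len(genes)), k)
    adj[rows, idx[:, 1:].ravel()] = True
    adj |= adj.T  # symmetrize

    d_idx = [genes.index(g) for g in dorsal_seeds]
    v_idx = [genes.index(g) for g in ventral_seeds]
    dorsal, ventral = set(dorsal_seeds), set(ventral_seeds)
    for i, g in enumerate(genes):
        if g in dorsal or g in ventral:
            continue
        nd = int(adj[i, d_idx].sum())
        nv = int(adj[i, v_idx].sum())
        if nd > nv and nd > 0:
            dorsal.add(g)
        elif nv > nd and nv > 0:
            ventral.add(g)
    return sorted(dorsal), sorted(ventral)


def fb_axis_scores(
    adata: ad.AnnData,
    modules: tuple[list[str], list[str]],
    seed: int = 0,
    n_bins: int = 24,
    n_ctrl: int = 100,
) -> pd.DataFrame:
    """Forebrain-axis scores from dorsal/ventral gene modules.

    ``DV_score = dorsal_score - ventral_score`` (expression-matched module
    scores); ``FBaxis_score`` equals the DV score on the forebrain subset, and
    ``FBaxis_rank`` ranks cells so the highest (most anterodorsal) score gets
    the highest rank.
    """
    dorsal_module, ventral_module = modules
    dorsal = module_score(adata, dorsal_module, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    ventral = module_score(adata, ventral_module, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + 1)
    dv = dorsal - ventral
    rank = pd.Series(rankdata(dv.values, method="ordinal"), index=dv.index)
    return pd.DataFrame(
        {
            "dorsal_score": dorsal,
            "ventral_score": ventral,
            "DV_score": dv,
            "FBaxis_score": dv,
            "FBaxis_rank": rank.astype(int),
        }
    )


def smooth_region_labels(
    latent: np.ndarray,
    labels: pd.Series | np.ndarray,
    k_neighbors: int = 15,
    regions: list[str] = AP_REGIONS,
) -> np.ndarray:
    """Jaccard-weighted k-nearest-neighbor label smoothening.

    For each cell, every labeled neighbor votes for its region with weight
    equal to the Jaccard overlap of the two cells' neighborhoods; the cell is
    reassigned to the highest-scoring region. Unlabeled cells (``None``)
    receive the winning label. Ties go to the region with more raw neighbor
    votes, then to the earlier region in ``regions``.
    """
    latent = np.asarray(latent, dtype=float)
    labels = np.asarray(labels, dtype=object)
    n = len(latent)
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(latent)
    _, idx = nn.kneighbors(latent)
    neigh = idx[:, 1:]
    neigh_sets = [set(row) for row in neigh]

    out = labels.copy()
    for i in range(n):
        scores = dict.fromkeys(regions, 0.0)
        votes = dict.fromkeys(regions, 0)
        for j in neigh[i]:
            lab = labels[j]
            if lab not in scores:
                continue
            inter = len(neigh_sets[i] & neigh_sets[j])
            union = len(neigh_sets[i] | neigh_sets[j])
            scores[lab] += inter / union if union else 0.0
            votes[lab] += 1
        best = max(regions, key=lambda r: (scores[r], votes[r], -regions.index(r)))
        if scores[best] > 0:
            out[i] = best
        elif out[i] is None:
            logger.warning("cell %d has no labeled neighbors; left unlabeled", i)
    return out


@dataclass
class APModel:
    """Elastic-net regression of region ordinal on a latent representation."""

    model: ElasticNetCV
    regions: list[str]


def train_ap_model(
    latent: np.ndarray,
    labels: pd.Series | np.ndarray,
    n_per_class: int = 5000,
    seed: int = 0,
    l1_ratio: float = 0.5,
) -> APModel:
    """Train the anteroposterior scoring model.

    Region labels are mapped to ordinals 1-4 (telencephalon to
    rhombencephalon), a balanced subsample of at most ``n_per_class`` cells
    per region is drawn, and an elastic net (penalty strength by internal
    cross-validation) regresses the ordinal on the latent coordinates.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 2 or latent.shape[1] < 2:
        raise ValueError("latent must be 2-D with at least 2 dimensions")
    if np.allclose(latent.std(axis=0), 0):
        raise ValueError("latent representation has zero variance")
    labels = np.asarray(labels, dtype=object)
    y = np.array([AP_ORDINAL.get(l, np.nan) for l in labels], dtype=float)
    mask = ~np.isnan(y)
    present = sorted(set(y[mask]))
    if len(present) < 2:
        raise ValueError("need at least 2 regions to train")
    missing = [r for r in AP_REGIONS if AP_ORDINAL[r] not in present]
    if missing:
        logger.warning("regions with no cells: %s; training on the rest", missing)
    rng = np.random.default_rng(seed)
    keep = []
    for v in present:
        pos = np.flatnonzero(mask & (y == v))
        if len(pos) > n_per_class:
            pos = rng.choice(pos, n_per_class, replace=False)
        keep.append(pos)
    keep = np.concatenate(keep)
    model = ElasticNetCV(l1_ratio=l1_ratio, cv=5, random_state=seed)
    model.fit(latent[keep], y[keep])
    return APModel(model, [r for r in AP_REGIONS if AP_ORDINAL[r] in present])


def predict_ap(model: APModel, latent: np.ndarray) -> np.ndarray:
    """Continuous anteroposterior score (1 anterior .. 4 posterior)."""
    return model.model.predict(np.asarray(latent, dtype=float))


@dataclass
class DVModel:
    """Penalized logistic classifier of dorsal vs ventral identity."""

    model: LogisticRegression
    threshold: float


def train_dv_model(
    latent: np.ndarray,
    marker_dv_scores: np.ndarray,
    threshold: float | None = None,
    train_fraction: float = 0.8,
    seed: int = 0,
    l1_ratio: float = 0.5,
) -> DVModel:
    """Train the dorsoventral scoring model from marker-based DV scores.

    Cells with ``|marker score| > threshold`` define the dorsal (positive) and
    ventral (negative) training classes; by default the threshold is the 80th
    percentile of the absolute scores (the absolute cutoff is configurable for
    data on other scales). A seeded random ``train_fraction`` subset trains an
    elastic-net-penalized logistic model.
    """
    latent = np.asarray(latent, dtype=float)
    scores = np.asarray(marker_dv_scores, dtype=float)
    if threshold is None:
        threshold = float(np.percentile(np.abs(scores), 80))
    dorsal = scores > threshold
    ventral = scores < -threshold
    if not dorsal.any() or not ventral.any():
        raise ValueError(
            f"threshold {threshold} leaves an empty dorsal or ventral class"
        )
    idx = np.flatnonzero(dorsal | ventral)
    rng = np.random.default_rng(seed)
    train = rng.choice(idx, size=max(2, int(round(train_fraction * len(idx)))), replace=False)
    y = dorsal[train].astype(int)
    if y.min() == y.max():  # degenerate split; fall back to all labeled cells
        train, y = idx, dorsal[idx].astype(int)
    model = LogisticRegression(solver="saga", l1_ratio=l1_ratio, C=1.0, max_iter=10_000)
    model.fit(latent[train], y)
    return DVModel(model, threshold)


def predict_dv(model: DVModel, latent: np.ndarray) -> np.ndarray:
    """Link-scale (linear predictor) DV score: positive dorsal, negative ventral."""
    return model.model.decision_function(np.asarray(latent, dtype=float))
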