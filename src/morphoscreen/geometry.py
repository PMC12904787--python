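"""Condition geometry: embeddings, distribution distances, reproducibility.

Conditions are summarized in a PCA of the RSS embedding (20 components by
default) and compared with distribution distances: kernel maximum mean
discrepancy (MMD, biased V-statistic), energy distance (E-distance, squared
Euclidean convention) and Kullback-Leibler divergence between cell-type
compositions. Lower values mean more similar conditions, i.e. higher
reproducibility when comparing replicates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import entropy
from sklearn.decomposition import PCA

logger = logging.getLogger("morphoscreen")


@dataclass
class ConditionEmbedding:
    """Cell coordinates in PCA space with per-cell group labels."""

    coords: pd.DataFrame
    explained_variance: np.ndarray
    components: np.ndarray
    mean: np.ndarray

    def group(self, labels: pd.Series, name) -> np.ndarray:
        return self.coords.values[np.asarray(labels) == name]


def condition_pca(rss: pd.DataFrame, k: int = 20) -> ConditionEmbedding:
    """Centered PCA of the RSS matrix, deterministic up to a fixed sign rule.

    Each component's sign is fixed so its largest-magnitude loading is
    positive. ``k`` larger than the matrix rank is reduced with a warning.
    """
    X = rss.values.astype(float)
    max_k = min(X.shape[0], X.shape[1])
    if k > max_k:
        logger.warning("k=%d exceeds rank bound %d; reduced", k, max_k)
        k = max_k
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    comps = pca.components_
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] *= -1
            coords[:, i] *= -1
    return ConditionEmbedding(
        coords=pd.DataFrame(coords, index=rss.index,
                            columns=[f"PC{i+1}" for i in range(k)]),
        explained_variance=pca.explained_variance_,
        components=comps,
        mean=pca.mean_,
    )


def _median_bandwidth(pooled: np.ndarray) -> float:
    d = pdist(pooled)
    return float(np.median(d)) if d.size else 0.0


def mmd_distance(
    A: np.ndarray,
    B: np.ndarray,
    kernel: str = "rbf-median",
    unbiased: bool = False,
) -> float:
    """Squared maximum mean discrepancy between two point samples.

    Biased V-statistic by default (identical samples give exactly 0, and the
    value is always >= 0); the RBF bandwidth is the median pairwise Euclidean
    distance over the pooled samples.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs at least 2 cells")
    if kernel == "rbf-median":
        bw = _median_bandwidth(np.vstack([A, B]))
        if bw == 0.0:
            return 0.0  # degenerate: all points identical
        gamma = 1.0 / (2.0 * bw * bw)
        k = lambda X, Y: np.exp(-gamma * cdist(X, Y, "sqeuclidean"))
    elif kernel == "linear":
        k = lambda X, Y: X @ Y.T
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    Kaa, Kbb, Kab = k(A, A), k(B, B), k(A, B)
    if unbiased:
        n, m = len(A), len(B)
        np.fill_diagonal(Kaa, 0.0)
        np.fill_diagonal(Kbb, 0.0)
        return float(
            Kaa.sum() / (n * (n - 1)) + Kbb.sum() / (m * (m - 1)) - 2 * Kab.mean()
        )
    return float(Kaa.mean() + Kbb.mean() - 2 * Kab.mean())


def energy_distance(A: np.ndarray, B: np.ndarray) -> float:
    """E-distance: 2 x mean between-group squared Euclidean distance minus
    the two within-group means (all-pairs means, so identical samples give 0).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs at least 2 cells")
    between = cdist(A, B, "sqeuclidean").mean()
    within_a = cdist(A, A, "sqeuclidean").mean()
    within_b = cdist(B, B, "sqeuclidean").mean()
    return float(2.0 * between - within_a - within_b)


def group_distance(
    emb: ConditionEmbedding,
    labels: pd.Series,
    group_a,
    group_b,
    metric: str = "mmd",
    kernel: str = "rbf-median",
) -> float:
    """Distance between two cell groups in the embedding."""
    A = emb.group(labels, group_a)
    B = emb.group(labels, group_b)
    if metric == "mmd":
        return mmd_distance(A, B, kernel=kernel)
    if metric == "edist":
        return energy_distance(A, B)
    raise ValueError(f"unknown metric {metric!r}")


def kld_composition(p_counts, q_counts, pseudocount: float = 1.0) -> float:
    """KL(p || q) between two cell-type count vectors (natural log).

    A pseudocount is added to the raw counts before normalization, so absent
    cell types never produce infinities.
    """
    p = np.asarray(p_counts, dtype=float) + pseudocount
    q = np.asarray(q_counts, dtype=float) + pseudocount
    if p.shape != q.shape:
        raise ValueError("compositions must share the same cell-type universe")
    return float(entropy(p, q))


def reproducibility_report(
    sample_meta: pd.DataFrame,
    compare: str = "batches",
    metric: str = "kld",
    compositions: pd.DataFrame | None = None,
    embeddings: dict | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Distances between replicate samples of the same treatment.

    ``sample_meta`` is one row per sample with columns ``treatment``,
    ``induction``, ``line``, ``batch``. In ``batches`` mode, samples are
    grouped by (treatment, induction, line) and each group's batch pair is
    compared; in ``lines`` mode samples are grouped by (treatment, induction)
    and all unordered sample pairs across lines/batches are compared. Groups
    with fewer than 2 samples are skipped with a log entry.

    ``metric="kld"`` uses ``compositions`` (sample x cell-type counts);
    ``"mmd"``/``"edist"`` use ``embeddings`` (sample -> cell-coordinate
    array). Returns a long-format table of pairs and distances.
    """
    if compare == "batches":
        keys = ["treatment", "induction", "line"]
    elif compare == "lines":
        keys = ["treatment", "induction"]
    else:
        raise ValueError(f"unknown compare mode {compare!r}")

    rows = []
    for group, sub in sample_meta.groupby(keys, sort=True):
        if len(sub) < 2:
            logger.info("group %s has <2 samples; skipped", group)
            continue
        for sa, sb in itertools.combinations(sub.index, 2):
            if metric == "kld":
                if compositions is None:
                    raise ValueError("kld metric requires compositions")
                value = kld_composition(
                    compositions.loc[sa], compositions.loc[sb], pseudocount
                )
                n_a = int(compositions.loc[sa].sum())
                n_b = int(compositions.loc[sb].sum())
            else:
                if embeddings is None:
                    raise ValueError(f"{metric} metric requires embeddings")
                A, B = embeddings[sa], embeddings[sb]
                value = mmd_distance(A, B) if metric == "mmd" else energy_distance(A, B)
                n_a, n_b = len(A), len(B)
            rows.append(
                dict(zip(keys, group if isinstance(group, tuple) else (group,)))
                | {
                    "sample_a": sa,
                    "sample_b": sb,
                    "metric": metric,
                    "value": value,
                    "n_a": n_a,
                    "n_b": n_b,
                }
            )
    return pd.DataFrame(rows)
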