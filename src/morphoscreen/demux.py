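"""Hashtag (HTO) demultiplexing: assign cells to sample-of-origin.

Cells are pooled across samples after barcoded-antibody labeling; each cell
carries counts for every hashtag oligo. Demultiplexing normalizes the counts
with a centered log-ratio (CLR) transform, finds a background cell set per
hashtag by clustering the CLR profiles, fits a negative-binomial background
distribution to the raw counts of those cells, and thresholds at a high
quantile of that background. A cell above threshold for exactly one hashtag is
a singlet; above for several, a doublet; above for none, a negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

logger = logging.getLogger("morphoscreen")

DOUBLET = "Doublet"
NEGATIVE = "Negative"


@dataclass
class HashtagCounts:
    """Cell x hashtag count matrix with optional CLR layer and calls."""

    counts: pd.DataFrame
    clr: pd.DataFrame | None = None
    call: pd.Series | None = None
    thresholds: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("hashtag counts must be non-negative")

    @property
    def hashtags(self) -> list[str]:
        return list(self.counts.columns)


def clr_normalize(h: HashtagCounts, margin: str = "within_cell") -> HashtagCounts:
    """Centered log-ratio transform of hashtag counts.

    ``clr[i, j] = ln(x_ij + 1) - mean_j ln(x_ij + 1)``, centered across
    hashtags within each cell (``margin="within_cell"``, the compositional
    direction). ``margin="across_cells"`` centers each hashtag across cells
    instead, matching some tool defaults.
    """
    if h.counts.shape[1] < 2:
        raise ValueError("CLR requires at least 2 hashtags")
    logx = np.log1p(h.counts.values.astype(np.float64))
    if margin == "within_cell":
        clr = logx - logx.mean(axis=1, keepdims=True)
    elif margin == "across_cells":
        clr = logx - logx.mean(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown margin {margin!r}")
    return replace(h, clr=pd.DataFrame(clr, index=h.counts.index, columns=h.counts.columns))


def _nb_quantile(x: np.ndarray, q: float) -> float:
    """Quantile of a negative binomial fit to x by method of moments.

    Falls back to Poisson when the sample is underdispersed.
    """
    m = float(np.mean(x))
    v = float(np.var(x))
    if m <= 0:
        return 0.0
    if v <= m:
        return float(stats.poisson.ppf(q, m))
    r = m * m / (v - m)
    p = r / (r + m)
    return float(stats.nbinom.ppf(q, r, p))


def demux_hashtags(
    h: HashtagCounts,
    positive_quantile: float = 0.99,
    seed: int = 0,
) -> HashtagCounts:
    """Call each cell as a hashtag singlet, Doublet or Negative.

    For each hashtag, cells whose CLR cluster does not maximize that hashtag
    form the background set; a negative binomial is fit to their raw counts
    (method of moments) and the ``positive_quantile`` quantile of the fit is
    the positivity threshold. Raising the quantile raises every threshold, so
    a Negative can never become a singlet.
    """
    if h.clr is None:
        raise ValueError("CLR layer required; run clr_normalize first")
    if not 0.5 < positive_quantile < 1:
        raise ValueError("positive_quantile must be in (0.5, 1)")
    counts = h.counts.values
    n_cells, n_tags = counts.shape
    k = min(n_tags, n_cells)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    clusters = km.fit_predict(h.clr.values)

    thresholds = np.empty(n_tags)
    for j in range(n_tags):
        # positive cluster: highest mean CLR for hashtag j
        cluster_means = np.array(
            [h.clr.values[clusters == c, j].mean() for c in range(k)]
        )
        pos_cluster = int(np.argmax(cluster_means))
        background = counts[clusters != pos_cluster, j]
        if background.size == 0:
            logger.warning(
                "hashtag %s: empty background set; falling back to global lower half",
                h.counts.columns[j],
            )
            col = np.sort(counts[:, j])
            background = col[: max(1, n_cells // 2)]
        thresholds[j] = _nb_quantile(background, positive_quantile)

    positive = counts > thresholds[None, :]
    n_pos = positive.sum(axis=1)
    call = np.where(
        n_pos == 0,
        NEGATIVE,
        np.where(n_pos > 1, DOUBLET, np.asarray(h.counts.columns)[positive.argmax(axis=1)]),
    )
    return replace(
        h,
        call=pd.Series(call, index=h.counts.index, name="hash_call"),
        thresholds=pd.Series(thresholds, index=h.counts.columns),
    )
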