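"""Morphogen-combination effects: NNLS non-additivity and added-morphogen MMD.

For each (single A, single B, combination AB) triple, the control-centered
centroid of the combination condition is expressed as a non-negative linear
combination of the single-treatment centroids; the residual norm of that fit
measures non-additivity of the morphogen interaction (the higher the
residual, the stronger the interaction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .geometry import ConditionEmbedding, mmd_distance

logger = logging.getLogger("morphoscreen")


@dataclass
class InteractionResult:
    """Non-negative decomposition of a combination centroid."""

    coef_a: float
    coef_b: float
    residual: float  # Euclidean norm of the unexplained component


def centered_centroids(
    emb: ConditionEmbedding, labels: pd.Series, control_label
) -> pd.DataFrame:
    """Per-condition centroids with the control centroid subtracted.

    The control condition maps exactly to the origin, making the origin a
    meaningful "no treatment" reference for the non-negative decomposition.
    """
    labels = pd.Series(np.asarray(labels), index=emb.coords.index)
    if control_label not in set(labels):
        raise ValueError(f"control condition {control_label!r} not present")
    centroids = emb.coords.groupby(labels).mean()
    return centroids - centroids.loc[control_label]


def nnls_interaction(
    centroid_a: np.ndarray,
    centroid_b: np.ndarray,
    centroid_ab: np.ndarray,
    squared: bool = False,
) -> InteractionResult:
    """Fit ``centroid_ab ~ a * centroid_a + b * centroid_b`` with a, b >= 0.

    Returns the coefficients and the minimized residual norm (Euclidean, or
    squared when ``squared=True``). The residual is 0 exactly when the
    combination centroid lies in the non-negative cone of the single
    centroids, and is invariant to any common rotation of the three vectors.
    """
    ca = np.asarray(centroid_a, dtype=float).ravel()
    cb = np.asarray(centroid_b, dtype=float).ravel()
    cab = np.asarray(centroid_ab, dtype=float).ravel()
    if not (ca.shape == cb.shape == cab.shape) or ca.size < 2:
        raise ValueError("centroids must share a common dimension >= 2")
    M = np.column_stack([ca, cb])
    if not M.any():
        res = float(np.linalg.norm(cab))
        return InteractionResult(0.0, 0.0, res * res if squared else res)
    coef, rnorm = nnls(M, cab)
    return InteractionResult(
        float(coef[0]), float(coef[1]), rnorm * rnorm if squared else float(rnorm)
    )


def interaction_screen(
    emb: ConditionEmbedding,
    labels: pd.Series,
    triples: list[tuple],
    control_label,
    squared: bool = False,
) -> pd.DataFrame:
    """NNLS decomposition plus MMD contrasts for (A, B, AB) condition triples.

    Each triple names two single-morphogen conditions and their combination
    condition. Returns a table with the non-negative coefficients, the
    non-additivity residual, and the MMD of the combination against each
    single treatment.
    """
    centroids = centered_centroids(emb, labels, control_label)
    lab = np.asarray(labels)
    rows = []
    for a, b, ab in triples:
        missing = [c for c in (a, b, ab) if c not in centroids.index]
        if missing:
            logger.warning("triple (%s, %s, %s): missing %s; skipped", a, b, ab, missing)
            continue
        fit = nnls_interaction(centroids.loc[a], centroids.loc[b], centroids.loc[ab], squared)
        X = emb.coords.values
        rows.append(
            {
                "single_a": a,
                "single_b": b,
                "combination": ab,
                "coef_a": fit.coef_a,
                "coef_b": fit.coef_b,
                "residual": fit.residual,
                "mmd_vs_a": mmd_distance(X[lab == ab], X[lab == a]),
                "mmd_vs_b": mmd_distance(X[lab == ab], X[lab == b]),
            }
        )
    return pd.DataFrame(rows)


def added_morphogen_effect(
    emb: ConditionEmbedding,
    labels: pd.Series,
    pairs: list[tuple],
) -> pd.DataFrame:
    """MMD between each condition and its counterpart with an added morphogen.

    ``pairs`` lists (condition, condition_plus_added) names; unmatched pairs
    are skipped with a warning.
    """
    lab = np.asarray(labels)
    present = set(lab)
    X = emb.coords.values
    rows = []
    for base, plus in pairs:
        if base not in present or plus not in present:
            logger.warning("pair (%s, %s) not found; skipped", base, plus)
            continue
        A, B = X[lab == base], X[lab == plus]
        rows.append(
            {
                "condition": base,
                "condition_plus": plus,
                "metric": "mmd",
                "value": mmd_distance(A, B),
                "n_a": len(A),
                "n_b": len(B),
            }
        )
    return pd.DataFrame(rows)
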