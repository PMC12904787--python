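"""Cell-type composition tables, Shannon diversity and Fisher enrichment.

Per-condition compositions are compared against the control condition with a
two-sided Fisher exact test per (condition, cluster) 2x2 table; the enrichment
score is the log2 of the conditional maximum-likelihood odds ratio, clamped to
+/-5, and set to 0 unless the Bonferroni-adjusted p-value is below 0.01.
Tests are performed separately per cell line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import gammaln

logger = logging.getLogger("morphoscreen")


@dataclass
class CompositionTable:
    """Condition x cell-type counts with proportions."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("composition counts must be non-negative")

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def proportions(self) -> pd.DataFrame:
        return self.counts.div(self.totals, axis=0)


def composition_table(
    meta: pd.DataFrame,
    condition_col: str = "condition",
    type_col: str = "cell_type",
) -> CompositionTable:
    """Tabulate per-condition cell-type counts from cell metadata."""
    counts = pd.crosstab(meta[condition_col], meta[type_col])
    return CompositionTable(counts)


def shannon_diversity(proportions) -> float:
    """Shannon diversity H = -sum p ln p (natural log).

    Lower values indicate a more homogeneous cell-type composition. Input is
    renormalized; zero entries contribute nothing.
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero composition has no diversity")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def _nchg_log_weights(support: np.ndarray, n1: int, n2: int, m1: int) -> np.ndarray:
    """Central (psi=1) log-weights of Fisher's noncentral hypergeometric."""
    return (
        gammaln(n1 + 1) - gammaln(support + 1) - gammaln(n1 - support + 1)
        + gammaln(n2 + 1) - gammaln(m1 - support + 1) - gammaln(n2 - m1 + support + 1)
    )


def conditional_mle_or(a: int, b: int, c: int, d: int) -> float:
    """Conditional maximum-likelihood odds ratio of a 2x2 table.

    The odds ratio maximizing Fisher's noncentral hypergeometric likelihood
    with all margins fixed — the estimate reported by the classical exact
    test. For an exponential family the maximizer solves the score equation
    ``E_psi[A] = a``, with E monotone in psi. Returns 0 or inf when ``a``
    sits at the boundary of the support.
    """
    n1, n2, m1 = a + b, c + d, a + c
    lo, hi = max(0, m1 - n2), min(n1, m1)
    if lo == hi:  # degenerate support: OR unidentified, conventionally 1
        return 1.0
    if a <= lo:
        return 0.0
    if a >= hi:
        return np.inf
    support = np.arange(lo, hi + 1)
    logw = _nchg_log_weights(support, n1, n2, m1)

    def f(t: float) -> float:
        lp = logw + support * t
        lp -= lp.max()
        w = np.exp(lp)
        return float((support * w).sum() / w.sum()) - a

    t_lo, t_hi = -1.0, 1.0
    while f(t_lo) > 0:
        t_lo *= 2
        if t_lo < -500:
            return 0.0
    while f(t_hi) < 0:
        t_hi *= 2
        if t_hi > 500:
            return np.inf
    return float(np.exp(brentq(f, t_lo, t_hi, xtol=1e-13)))


def fisher_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value by point-probability ordering.

    Sums the central hypergeometric probabilities of all tables (with the
    observed margins) no more likely than the observed one, with the
    conventional ``1 + 1e-7`` relative slack on the comparison (the classical
    R convention for the exact test on count data).
    """
    n1, n2, m1 = a + b, c + d, a + c
    lo, hi = max(0, m1 - n2), min(n1, m1)
    support = np.arange(lo, hi + 1)
    logw = _nchg_log_weights(support, n1, n2, m1)
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    p_obs = w[a - lo]
    return float(min(1.0, w[w <= p_obs * (1 + 1e-7)].sum()))


def fisher_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact p (point-probability ordering) and cMLE OR."""
    return fisher_pvalue(a, b, c, d), conditional_mle_or(a, b, c, d)


def fisher_enrichment(
    comp: CompositionTable,
    control_condition: str,
    alpha: float = 0.01,
    cap: float = 5.0,
    lines: pd.Series | None = None,
) -> pd.DataFrame:
    """Enrichment/depletion scores of every (condition, cluster) vs control.

    For each non-control condition and cluster a 2x2 table (in-cluster vs
    out-of-cluster, treated vs control) is tested with a two-sided Fisher
    exact test. P-values are Bonferroni-adjusted over all tests within the
    same cell line (``lines`` maps condition -> line; one family when absent).
    The score is ``clamp(log2(cMLE odds ratio), -cap, +cap)`` when the
    adjusted p is below ``alpha`` and 0 otherwise; a zero or infinite odds
    ratio maps to -cap/+cap when significant. Clusters absent from both the
    condition and the control are skipped.
    """
    counts = comp.counts
    if control_condition not in counts.index:
        raise ValueError(f"control condition {control_condition!r} not present")
    ctrl = counts.loc[control_condition]
    n_ctrl = int(ctrl.sum())
    if n_ctrl < 1:
        raise ValueError("control condition has no cells")
    if lines is None:
        lines = pd.Series("all", index=counts.index)

    rows = []
    for cond in counts.index:
        if cond == control_condition:
            continue
        n_cond = int(counts.loc[cond].sum())
        for cluster in counts.columns:
            a = int(counts.loc[cond, cluster])
            c = int(ctrl[cluster])
            if a + c == 0:
                continue  # cluster absent from both groups
            b, d = n_cond - a, n_ctrl - c
            p, orr = fisher_test(a, b, c, d)
            rows.append(
                {
                    "condition": cond,
                    "cluster": cluster,
                    "line": lines.get(cond, "all"),
                    "a": a, "b": b, "c": c, "d": d,
                    "odds_ratio": orr,
                    "p_raw": p,
                }
            )
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["p_adj"] = res.groupby("line")["p_raw"].transform(
        lambda p: np.minimum(p * len(p), 1.0)
    )
    with np.errstate(divide="ignore"):
        log2_or = np.log2(res["odds_ratio"].values)
    score = np.clip(log2_or, -cap, cap)
    score[np.isnan(score)] = 0.0
    res["score"] = np.where(res["p_adj"] < alpha, score, 0.0)
    res["n"] = res["a"] + res["b"]
    return res
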