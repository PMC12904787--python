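"""Morphogen-regulon network inference from regulon activity matrices.

Each morphogen is represented by pseudo-variables — a scaled dose column, a
timing column (treatment-window start day) and, optionally, pairwise
dose-interaction columns. A tree-ensemble regression predicts each design
column from all regulon activities; the total impurity importance of a regulon
(scaled by cell number) is the weight of the (column, regulon) link. Links
found through interaction or timing columns are demultiplexed back to their
parent morphogens with kind flags, keeping the strongest connection per
(morphogen, regulon) pair; links are then annotated with Pearson correlations
to timing and concentration and tested for non-linearity with the Ramsey RESET
test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.diagnostic import linear_reset

logger = logging.getLogger("morphoscreen")

#: full-scale weight threshold for retaining links
DEFAULT_WEIGHT_THRESHOLD = 200.0


@dataclass
class MorphogenDesign:
    """Per-cell pseudo-morphogen design matrix with column bookkeeping.

    ``columns`` maps each design column to ``(morphogens, kind)`` where kind
    is ``dose``, ``time`` or ``interaction``. Dose columns are ln(1+dose)
    min-max scaled to [0, 1]; timing columns hold the exposure-start day (0
    for untreated cells); interaction columns are elementwise products of
    their parents' scaled doses.
    """

    matrix: pd.DataFrame
    columns: dict[str, tuple[tuple[str, ...], str]]


def build_design(
    meta: pd.DataFrame,
    interactions: list[tuple[str, str]] | None = None,
    include_timing: bool = True,
) -> MorphogenDesign:
    """Build the pseudo-morphogen design matrix from cell metadata.

    Requires ``dose_<morphogen>`` columns and a ``t_start`` column. Morphogens
    whose dose never varies are dropped with a warning.
    """
    dose_cols = sorted(c for c in meta.columns if c.startswith("dose_"))
    if not dose_cols:
        raise ValueError("metadata has no dose_* columns")
    if include_timing and "t_start" not in meta.columns:
        raise ValueError("metadata has no t_start column")
    data: dict[str, np.ndarray] = {}
    book: dict[str, tuple[tuple[str, ...], str]] = {}
    scaled: dict[str, np.ndarray] = {}
    for col in dose_cols:
        m = col[len("dose_"):]
        x = np.log1p(meta[col].values.astype(float))
        lo, hi = x.min(), x.max()
        if hi == lo:
            logger.warning("morphogen %s never varies; dropped from design", m)
            continue
        scaled[m] = (x - lo) / (hi - lo)
        data[m] = scaled[m]
        book[m] = ((m,), "dose")
    if include_timing:
        for m in list(scaled):
            t = np.where(meta[f"dose_{m}"].values > 0, meta["t_start"].values.astype(float), 0.0)
            name = f"{m}:time"
            data[name] = t
            book[name] = ((m,), "time")
    for m1, m2 in interactions or []:
        if m1 not in scaled or m2 not in scaled:
            logger.warning("interaction (%s, %s) references a dropped morphogen; skipped", m1, m2)
            continue
        name = f"{m1}*{m2}"
        data[name] = scaled[m1] * scaled[m2]
        book[name] = (tuple(sorted((m1, m2))), "interaction")
    return MorphogenDesign(pd.DataFrame(data, index=meta.index), book)


def link_regulons(
    activity: pd.DataFrame,
    design: MorphogenDesign,
    n_estimators: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw (design column, regulon, weight) links by tree-ensemble importance.

    For every design column a random-forest regression predicts the column
    from all regulon activities; the weight of each regulon is its total
    impurity importance scaled by the number of cells, so magnitudes are
    comparable across runs of different size. Constant design columns are
    skipped.
    """
    if activity.shape[1] == 0:
        raise ValueError("no regulons in the activity matrix")
    shared = activity.index.intersection(design.matrix.index)
    if len(shared) == 0:
        raise ValueError("activity and design share no cells")
    A = activity.loc[shared]
    D = design.matrix.loc[shared]
    n_cells = len(shared)
    rows = []
    for j, col in enumerate(D.columns):
        y = D[col].values
        if np.ptp(y) == 0:
            logger.warning("design column %s is constant; skipped", col)
            continue
        rf = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=seed + j,
            n_jobs=1,
        )
        rf.fit(A.values, y)
        for regulon, imp in zip(A.columns, rf.feature_importances_):
            rows.append({"column": col, "regulon": regulon, "weight": imp * n_cells})
    return pd.DataFrame(rows)


def demultiplex_links(
    raw: pd.DataFrame,
    design: MorphogenDesign,
    weight_threshold: float = DEFAULT_WEIGHT_THRESHOLD,
) -> pd.DataFrame:
    """Collapse raw column-level links onto single morphogens.

    Interaction and timing columns contribute their weight to each parent
    morphogen, flagged with the column kind; per (morphogen, regulon) only the
    strongest connection is retained, then links below ``weight_threshold``
    are discarded. Every retained weight traces back to exactly one raw
    (column, regulon) pair, recorded in ``source_column``.
    """
    rows = []
    for _, r in raw.iterrows():
        morphogens, kind = design.columns[r["column"]]
        for m in morphogens:
            rows.append(
                {
                    "morphogen": m,
                    "regulon": r["regulon"],
                    "weight": r["weight"],
                    "kind": kind,
                    "source_column": r["column"],
                }
            )
    links = pd.DataFrame(rows)
    if links.empty:
        return links
    links = (
        links.sort_values("weight", ascending=False)
        .drop_duplicates(["morphogen", "regulon"], keep="first")
        .reset_index(drop=True)
    )
    return links[links["weight"] > weight_threshold].reset_index(drop=True)


def annotate_correlations(
    links: pd.DataFrame,
    activity: pd.DataFrame,
    meta: pd.DataFrame,
    series_col: str = "series",
    subsample_per_condition: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Annotate links with timing and concentration Pearson correlations.

    ``meta[series_col]`` marks each cell as belonging to ``timing`` or
    ``concentration`` experiment series. Per link, ``r_concentration`` is the
    Pearson correlation of the regulon activity with the morphogen dose among
    concentration-series cells, and ``r_timing`` with the treatment-window
    start among timing-series cells treated with that morphogen. Cells can be
    subsampled to equal numbers per condition (seeded). Fewer than 3 distinct
    x-values give NaN.
    """
    meta = meta.loc[activity.index]
    if subsample_per_condition is not None:
        rng = np.random.default_rng(seed)
        keep: list = []
        for _, idx in meta.groupby("condition").groups.items():
            idx = list(idx)
            if len(idx) > subsample_per_condition:
                idx = list(rng.choice(idx, subsample_per_condition, replace=False))
            keep.extend(idx)
        meta = meta.loc[keep]
        activity = activity.loc[keep]

    series = meta[series_col] if series_col in meta.columns else pd.Series("concentration", index=meta.index)

    def _corr(x: np.ndarray, y: np.ndarray) -> float:
        if len(x) < 3 or np.unique(x).size < 3 or np.std(y) == 0:
            return np.nan
        return float(pearsonr(x, y)[0])

    r_conc, r_time = [], []
    for _, link in links.iterrows():
        m, reg = link["morphogen"], link["regulon"]
        dose = meta[f"dose_{m}"].values.astype(float)
        act = activity[reg].values
        conc = (series == "concentration").values
        r_conc.append(_corr(dose[conc], act[conc]))
        timing = (series == "timing").values & (dose > 0)
        r_time.append(_corr(meta["t_start"].values[timing], act[timing]))
    out = links.copy()
    out["r_concentration"] = r_conc
    out["r_timing"] = r_time
    return out


def reset_test(activity: np.ndarray, dose: np.ndarray, powers: tuple[int, ...] = (2, 3)) -> float:
    """Ramsey RESET p-value for non-linearity of activity in dose.

    Fits OLS of activity on dose, augments with the given powers of the fitted
    values and F-tests the joint nullity of the augmentation terms. A small p
    indicates the linear model is misspecified (a non-linear link). Returns
    NaN with a warning when the augmentation is collinear.
    """
    activity = np.asarray(activity, dtype=float)
    dose = np.asarray(dose, dtype=float)
    if activity.size < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(dose) == 0:
        raise ValueError("dose is constant")
    X = sm.add_constant(dose)
    res = sm.OLS(activity, X).fit()
    total_ss = float(np.sum((activity - activity.mean()) ** 2))
    if res.ssr <= 1e-12 * max(total_ss, 1e-300):
        return 1.0  # linear fit already exact; augmentation can add nothing
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            test = linear_reset(res, power=list(powers), test_type="fitted", use_f=True)
        p = float(test.pvalue)
    except Exception as exc:  # collinear augmentation
        logger.warning("RESET test failed (%s); returning NaN", exc)
        return np.nan
    if np.isnan(p):
        logger.warning("RESET augmentation collinear; returning NaN")
    return p


def annotate_nonlinearity(
    links: pd.DataFrame,
    activity: pd.DataFrame,
    meta: pd.DataFrame,
    powers: tuple[int, ...] = (2, 3),
) -> pd.DataFrame:
    """Add a RESET non-linearity p-value per link."""
    meta = meta.loc[activity.index]
    ps = []
    for _, link in links.iterrows():
        dose = meta[f"dose_{link['morphogen']}"].values.astype(float)
        try:
            ps.append(reset_test(activity[link["regulon"]].values, dose, powers))
        except ValueError:
            ps.append(np.nan)
    out = links.copy()
    out["reset_p"] = ps
    return out


def consensus_regulons(
    runs: list[dict[str, list[str] | set[str]]],
    min_fraction: float = 0.5,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Summarize repeated regulon-discovery runs into consensus regulons.

    A TF detected in fewer than ``min_fraction`` of all runs is dropped; for a
    retained TF, a target is kept when it appears in at least ``min_fraction``
    of the runs in which that TF was detected. Returns the consensus
    collection and a per-edge support table (TF, target, support fraction).
    """
    if not runs:
        raise ValueError("no runs provided")
    n_runs = len(runs)
    tf_runs: dict[str, int] = {}
    edge_runs: dict[tuple[str, str], int] = {}
    for run in runs:
        for tf, targets in run.items():
            tf_runs[tf] = tf_runs.get(tf, 0) + 1
            for t in targets:
                edge_runs[(tf, t)] = edge_runs.get((tf, t), 0) + 1
    consensus: dict[str, list[str]] = {}
    rows = []
    for tf, n_det in sorted(tf_runs.items()):
        if n_det / n_runs < min_fraction:
            continue
        targets = []
        for (tf2, t), n_edge in edge_runs.items():
            if tf2 != tf:
                continue
            support = n_edge / n_det
            rows.append({"tf": tf, "target": t, "support": support})
            if support >= min_fraction:
                targets.append(t)
        consensus[tf] = sorted(targets)
    return consensus, pd.DataFrame(rows)
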