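"""Synthetic morphogen-patterning screens with known ground truth.

The generator emulates the data structure of a pooled neural-organoid
patterning screen read out by single-cell RNA-seq with cell hashing:

* a reference atlas of region profiles (cluster-averaged expression with
  anteroposterior ordinals and a dorsal/ventral flag);
* per-condition cell-type compositions driven by an additive logit model in
  morphogen dose, pairwise dose interactions and treatment-window start;
* cluster-specific negative-binomial expression with dorsoventrally graded
  marker genes;
* regulon activities that respond (linearly or non-linearly) to dose;
* hashtag counts with singlet/doublet/negative structure.

Every stochastic step is driven by a single integer seed, and the full ground
truth (compositions, latent dorsoventral coordinates, true morphogen-regulon
links, true hashtag identities) is returned so downstream estimates can be
scored against a known answer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .demux import HashtagCounts
from .io import make_screen

logger = logging.getLogger("morphoscreen")

#: concentration-step ladder: c1..c5 on a log2-spaced fraction of dose_max
DOSE_LADDER = {"c1": 0.0625, "c2": 0.125, "c3": 0.25, "c4": 0.5, "c5": 1.0}
STEPS = tuple(DOSE_LADDER)


class DesignError(ValueError):
    """Raised for invalid screen designs (e.g. no control condition)."""


@dataclass(frozen=True)
class ConditionSpec:
    """One treatment condition of the screen.

    ``morphogens`` and ``dose_steps`` are parallel: each morphogen is applied
    at the concentration step named by ``dose_steps`` (c1..c5, mapped to a
    numeric dose on a log2-spaced ladder times ``dose_max``). ``window`` is
    the treatment window in days within the 21-day protocol. A control
    condition has no morphogens and all doses zero.
    """

    name: str
    morphogens: tuple[str, ...] = ()
    dose_steps: tuple[str, ...] = ()
    window: tuple[float, float] = (0.0, 21.0)
    line: str = "HES3"
    batch: str = "b1"
    induction: str = "MNIM"
    dose_max: float = 1.0

    def __post_init__(self) -> None:
        if len(self.morphogens) != len(self.dose_steps):
            raise ValueError("morphogens and dose_steps must be parallel")
        for s in self.dose_steps:
            if s not in DOSE_LADDER:
                raise ValueError(f"unknown dose step {s!r}")
        t0, t1 = self.window
        if not (0 <= t0 < t1 <= 21):
            raise ValueError(f"invalid treatment window {self.window}")

    @property
    def is_control(self) -> bool:
        return len(self.morphogens) == 0

    def dose(self, morphogen: str) -> float:
        """Numeric dose of ``morphogen`` (0 when not applied)."""
        for m, s in zip(self.morphogens, self.dose_steps):
            if m == morphogen:
                return DOSE_LADDER[s] * self.dose_max
        return 0.0

    @property
    def doses(self) -> dict[str, float]:
        return {m: DOSE_LADDER[s] * self.dose_max for m, s in zip(self.morphogens, self.dose_steps)}


class TrueLink(NamedTuple):
    """A ground-truth morphogen-regulon link."""

    morphogen: str
    regulon: str
    sign: int
    is_nonlinear: bool = False


@dataclass
class ReferenceAtlas:
    """Region-labeled mean expression profiles.

    ``profiles`` is region x gene on a linear (non-negative) scale; each
    region has a disjoint block of marker genes elevated over background.
    ``ap_ordinal`` orders regions along the anteroposterior axis (1-4);
    ``dorsal`` flags dorsal regions.
    """

    profiles: pd.DataFrame
    ap_ordinal: pd.Series
    dorsal: pd.Series
    marker_genes: dict[str, list[str]]

    @property
    def regions(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def genes(self) -> list[str]:
        return list(self.profiles.columns)


@dataclass
class ScreenEffects:
    """Parameters of the additive composition-logit model.

    Per (condition, cell type) the logit is::

        base[k] + sum_m beta[(k, m)] * dose_m
                + sum_(m1,m2) gamma[(k, (m1, m2))] * dose_m1 * dose_m2
                + sum_m tau[(k, m)] * window_start   (for applied morphogens)

    and compositions are the softmax of the logits.
    """

    base: dict[str, float] = field(default_factory=dict)
    beta: dict[tuple[str, str], float] = field(default_factory=dict)
    gamma: dict[tuple[str, tuple[str, str]], float] = field(default_factory=dict)
    tau: dict[tuple[str, str], float] = field(default_factory=dict)

    def logits(self, cond: ConditionSpec, cell_types: list[str]) -> np.ndarray:
        doses = cond.doses
        t_start = cond.window[0]
        out = np.zeros(len(cell_types))
        for i, k in enumerate(cell_types):
            z = self.base.get(k, 0.0)
            for m, d in doses.items():
                z += self.beta.get((k, m), 0.0) * d
                z += self.tau.get((k, m), 0.0) * t_start
            for (m1, m2) in itertools.combinations(sorted(doses), 2):
                g = self.gamma.get((k, (m1, m2)), 0.0) or self.gamma.get((k, (m2, m1)), 0.0)
                z += g * doses[m1] * doses[m2]
            out[i] = z
        return out


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    composition_logits: pd.DataFrame
    cell_type: pd.Series
    dv_position: pd.Series
    ap_region: pd.Series
    hash_identity: pd.Series
    true_links: list[TrueLink] = field(default_factory=list)

    def expected_composition(self) -> pd.DataFrame:
        """Softmax of the composition logits; rows sum to 1."""
        z = self.composition_logits.values
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        return pd.DataFrame(p, index=self.composition_logits.index,
                            columns=self.composition_logits.columns)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.composition_logits.to_csv(path / "composition_logits.tsv", sep="\t")
        per_cell = pd.DataFrame(
            {
                "cell_type": self.cell_type,
                "dv_position": self.dv_position,
                "ap_region": self.ap_region,
                "hash_identity": [
                    "+".join(h) if isinstance(h, tuple) else h for h in self.hash_identity
                ],
            }
        )
        per_cell.to_csv(path / "cells_truth.tsv", sep="\t", index_label="cell_id")
        pd.DataFrame(self.true_links).to_csv(path / "true_links.tsv", sep="\t", index=False)


def make_reference_atlas(
    n_regions: int,
    markers_per_region: int,
    n_genes: int,
    seed: int,
    marker_fold: float = 6.0,
    n_mito: int = 3,
) -> ReferenceAtlas:
    """Generate a synthetic reference atlas of region expression profiles.

    Each region receives a disjoint block of ``markers_per_region`` marker
    genes elevated ``marker_fold``-fold (>= 4) over a shared log-normal
    background. Regions carry anteroposterior ordinals 1-4 cyclically and an
    alternating dorsal/ventral flag. A few genes are named with an ``MT-``
    prefix to stand in for mitochondrial transcripts.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if markers_per_region * n_regions > n_genes:
        raise ValueError("marker blocks exceed the gene universe")
    if marker_fold < 4:
        raise ValueError("marker_fold must be >= 4")
    rng = np.random.default_rng(seed)
    regions = [f"region{r}" for r in range(n_regions)]
    genes = [f"g{i}" for i in range(n_genes)]
    # rename trailing non-marker genes to mitochondrial ids
    n_marker_total = markers_per_region * n_regions
    n_mito = min(n_mito, n_genes - n_marker_total)
    for i in range(n_mito):
        genes[n_genes - 1 - i] = f"MT-{i}"

    background = rng.lognormal(mean=0.0, sigma=0.4, size=n_genes) + 0.1
    profiles = np.tile(background, (n_regions, 1)) * rng.lognormal(
        0.0, 0.05, size=(n_regions, n_genes)
    )
    marker_genes: dict[str, list[str]] = {}
    for r in range(n_regions):
        block = slice(r * markers_per_region, (r + 1) * markers_per_region)
        profiles[r, block] *= marker_fold * rng.uniform(1.0, 1.5, markers_per_region)
        marker_genes[regions[r]] = genes[block]

    prof = pd.DataFrame(profiles, index=regions, columns=genes)
    ap = pd.Series([(r % 4) + 1 for r in range(n_regions)], index=regions, name="ap_ordinal")
    dorsal = pd.Series([r % 2 == 0 for r in range(n_regions)], index=regions, name="dorsal")
    return ReferenceAtlas(prof, ap, dorsal, marker_genes)


def composition_logit_table(
    design: list[ConditionSpec], atlas: ReferenceAtlas, effects: ScreenEffects
) -> pd.DataFrame:
    types = atlas.regions
    rows = [effects.logits(c, types) for c in design]
    return pd.DataFrame(rows, index=[c.name for c in design], columns=types)


def simulate_screen(
    design: list[ConditionSpec],
    atlas: ReferenceAtlas,
    cells_per_condition: int,
    effects: ScreenEffects | None = None,
    seed: int = 0,
    nb_dispersion: float = 0.5,
    total_counts: float = 2000.0,
    doublet_rate: float = 0.05,
    ambient_fraction: float = 0.02,
    negative_rate: float = 0.01,
    hash_signal: float = 150.0,
    dv_amplitude: float = 1.6,
):
    """Simulate a hashed patterning screen.

    Returns ``(experiment, hashtag_counts, ground_truth)``. Cell types are
    drawn per condition from the softmax of the composition logits; counts are
    negative binomial around the cell's region profile, with dorsal-region
    marker genes scaled up and ventral-region markers scaled down along each
    cell's latent dorsoventral coordinate. One hashtag per condition is
    simulated with Poisson signal plus ambient background; a ``doublet_rate``
    fraction of cells carry a second hashtag and a ``negative_rate`` fraction
    carry none.
    """
    if not design:
        raise DesignError("empty design")
    if not any(c.is_control for c in design):
        raise DesignError("design must contain at least one control condition")
    if effects is None:
        effects = ScreenEffects()
    rng = np.random.default_rng(seed)

    types = atlas.regions
    logit_table = composition_logit_table(design, atlas, effects)
    z = logit_table.values - logit_table.values.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)

    profiles = atlas.profiles.values
    genes = atlas.genes
    n_genes = len(genes)
    dorsal_marker_idx = np.array(
        [genes.index(g) for r in atlas.regions if atlas.dorsal[r] for g in atlas.marker_genes[r]],
        dtype=int,
    )
    ventral_marker_idx = np.array(
        [genes.index(g) for r in atlas.regions if not atlas.dorsal[r] for g in atlas.marker_genes[r]],
        dtype=int,
    )

    hashtags = [f"HTO-{c.name}" for c in design]
    obs_rows = []
    counts_blocks = []
    hash_rows = []
    truth_type, truth_dv, truth_ap, truth_hash = [], [], [], []
    all_morphogens = sorted({m for c in design for m in c.morphogens})
    r_disp = 1.0 / nb_dispersion

    for ci, cond in enumerate(design):
        type_idx = rng.choice(len(types), size=cells_per_condition, p=probs[ci])
        dorsal_flags = atlas.dorsal.values[type_idx]
        dv = np.where(
            dorsal_flags,
            rng.uniform(0.5, 1.0, cells_per_condition),
            rng.uniform(0.0, 0.5, cells_per_condition),
        )
        mu = profiles[type_idx].copy()
        if dorsal_marker_idx.size:
            mu[:, dorsal_marker_idx] *= (0.2 + dv_amplitude * dv)[:, None]
        if ventral_marker_idx.size:
            mu[:, ventral_marker_idx] *= (0.2 + dv_amplitude * (1.0 - dv))[:, None]
        mu *= total_counts / mu.sum(axis=1, keepdims=True)
        counts = rng.negative_binomial(r_disp, r_disp / (r_disp + mu))
        counts_blocks.append(sp.csr_matrix(counts))

        # hashtag identities and counts
        fate = rng.uniform(size=cells_per_condition)
        ambient = ambient_fraction * hash_signal
        hcounts = rng.poisson(ambient, size=(cells_per_condition, len(design)))
        for i in range(cells_per_condition):
            if fate[i] < negative_rate:
                truth_hash.append("Negative")
            elif fate[i] < negative_rate + doublet_rate and len(design) > 1:
                other = int(rng.choice([j for j in range(len(design)) if j != ci]))
                hcounts[i, ci] += rng.poisson(hash_signal)
                hcounts[i, other] += rng.poisson(hash_signal)
                truth_hash.append((hashtags[ci], hashtags[other]))
            else:
                hcounts[i, ci] += rng.poisson(hash_signal)
                truth_hash.append(hashtags[ci])
        hash_rows.append(hcounts)

        for i in range(cells_per_condition):
            row = {
                "condition": cond.name,
                "cell_type": types[type_idx[i]],
                "line": cond.line,
                "batch": cond.batch,
                "induction": cond.induction,
                "t_start": cond.window[0],
                "t_end": cond.window[1],
            }
            for m in all_morphogens:
                row[f"dose_{m}"] = cond.dose(m)
            obs_rows.append(row)
        truth_type.extend(types[t] for t in type_idx)
        truth_dv.extend(dv)
        truth_ap.extend(atlas.ap_ordinal.values[type_idx])

    cell_ids = [f"cell{i}" for i in range(len(obs_rows))]
    obs = pd.DataFrame(obs_rows, index=cell_ids)
    X = sp.vstack(counts_blocks).tocsr()
    var = pd.DataFrame(index=genes)
    var["mito"] = [g.startswith("MT-") for g in genes]
    adata = make_screen(X, obs, var)

    hashed = HashtagCounts(
        pd.DataFrame(np.vstack(hash_rows), index=cell_ids, columns=hashtags)
    )
    truth = GroundTruth(
        composition_logits=logit_table,
        cell_type=pd.Series(truth_type, index=cell_ids, name="cell_type"),
        dv_position=pd.Series(truth_dv, index=cell_ids, name="dv_position"),
        ap_region=pd.Series(truth_ap, index=cell_ids, name="ap_region"),
        hash_identity=pd.Series(truth_hash, index=cell_ids, name="hash_identity"),
    )
    return adata, hashed, truth


def simulate_regulon_activities(
    meta: pd.DataFrame,
    true_links: list[TrueLink],
    noise_sd: float = 0.05,
    seed: int = 0,
    n_regulons: int = 30,
) -> pd.DataFrame:
    """Simulate per-cell regulon activity (AUC-like, in [0, 1]).

    Linked regulons respond to the (min-max scaled) dose of their morphogen:
    linearly with the link's sign, or — when ``is_nonlinear`` — as a concave
    saturating quadratic 2d - d^2 (monotone, so the link keeps its sign, but
    clearly misspecified under a linear fit). Unlinked regulons are pure noise
    around a constant baseline. Requires ``dose_<morphogen>`` columns.
    """
    dose_cols = [c for c in meta.columns if c.startswith("dose_")]
    if not dose_cols:
        raise ValueError("metadata has no dose_* columns")
    rng = np.random.default_rng(seed)
    n = len(meta)
    linked = {ln.regulon: ln for ln in true_links}
    names = list(dict.fromkeys(list(linked) + [f"R{i}" for i in range(n_regulons)]))[:max(n_regulons, len(linked))]

    out = {}
    for name in names:
        if name in linked:
            ln = linked[name]
            col = f"dose_{ln.morphogen}"
            if col not in meta.columns:
                raise ValueError(f"morphogen {ln.morphogen!r} absent from metadata")
            d = meta[col].values.astype(float)
            dmax = d.max()
            d = d / dmax if dmax > 0 else d
            if ln.is_nonlinear:
                sat = 2.0 * d - d * d
                base = 0.2 + 0.6 * sat if ln.sign > 0 else 0.8 - 0.6 * sat
            elif ln.sign > 0:
                base = 0.2 + 0.6 * d
            else:
                base = 0.8 - 0.6 * d
        else:
            base = np.full(n, 0.3)
        act = base + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else base.copy()
        out[name] = np.clip(act, 0.0, 1.0)
    return pd.DataFrame(out, index=meta.index)


def make_random_regulons(
    genes: list[str], n_regulons: int, set_size: int, seed: int
) -> dict[str, list[str]]:
    """Random TF -> target gene sets over a gene universe (for scoring tests)."""
    rng = np.random.default_rng(seed)
    return {
        f"R{i}": sorted(rng.choice(genes, size=min(set_size, len(genes)), replace=False))
        for i in range(n_regulons)
    }
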