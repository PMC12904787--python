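# Methods

This note documents the statistical models and procedures implemented in
`morphoscreen`, the choices made where the design was genuinely open, and the
limits of what the synthetic validation can show.

## Screen representation

A screen is an `AnnData`: raw UMI counts in `.X` (sparse integers), cell
metadata in `.obs` (condition, per-morphogen numeric dose columns `dose_<m>`,
treatment window `t_start`/`t_end` in days, line, batch, induction method),
gene metadata in `.var` (with a boolean `mito` flag), and the log-normalized
layer in `.layers["lognorm"]`. Concentration steps c1–c5 map to a log2-spaced
dose ladder {0.0625, 0.125, 0.25, 0.5, 1} × `dose_max`; only the ladder's
shape matters downstream (correlations and design matrices re-scale doses),
so `dose_max` defaults to 1 in arbitrary units.

QC keeps cells with ≥ 1,000 detected (nonzero) genes and mitochondrial UMI
fraction strictly below 10% — "lower than 1,000" and "10% or higher" are
removal rules, so retention is `≥` and `<` respectively. Optional exclusive
UMI bounds (750, 20,000) support the reproducibility-screen style of
filtering. Normalization is `ln(1 + 10^4 · x / total)` per cell; a zero-total
cell is an error naming the cell rather than a silent NaN.

## Hashtag demultiplexing

Counts are CLR-transformed within each cell across hashtags (the
compositional margin; the across-cells margin is available as an option since
tool defaults differ). Cells are clustered on the CLR profiles with seeded
k-means, k = number of hashtags. For each hashtag, the cells outside the
cluster that maximizes it form its background; a negative binomial is fit to
their raw counts by method of moments (Poisson fallback when underdispersed),
and the positivity threshold is the fit's `positive_quantile` quantile
(default 0.99; the original workflow tuned 0.99–0.999 per sample without
stating criteria, so it is exposed as configuration only). Cells above
threshold for exactly one hashtag are singlets; for several, doublets; for
none, negatives. Thresholds are monotone in the quantile, so raising it can
only move calls toward Negative, never create new singlets.

## RSS, AUCell and module scores

The reference similarity spectrum correlates each cell's log-normalized
profile with each reference cluster profile over shared genes (Spearman by
default — the similarity kernel of the underlying method is not fixed in the
source workflow, and rank correlation buys invariance to monotone per-gene
transformations; Pearson is an option), then z-scores the correlation vector
within the cell. Constant cells get zero rows with a warning.

AUCell activity ranks genes per cell (descending expression) and scores a
gene set by the area under its recovery step curve within the top
`top_fraction` of ranks (default 0.05, the scoring convention of the original
tool; not stated by the workflow, configurable), normalized so a set packing
the very top ranks scores exactly 1. Expression ties are broken
deterministically by higher global mean expression then gene id; a seeded
random tie-break is available. Scores are invariant to positive rescaling of
a cell.

Module scores subtract expression-matched controls: per-gene mean expression
is cut into `n_bins = 24` equal-frequency bins, and each set gene draws
`n_ctrl = 100` control genes with replacement from its own bin (the cited
function's conventions; the workflow states none). The score is mean(set) −
mean(controls). Control draws may include set genes — with sparse set
membership per bin the bias is O(1/bin size).

## Composition statistics

Shannon diversity uses the natural log (the workflow does not state a base).
Enrichment testing builds, per non-control condition and cluster, the 2×2
table (in/out of cluster × treated/control) and computes a two-sided Fisher
exact p by point-probability ordering with the classical 1+1e-7 relative
slack. The p-value is computed by direct tail enumeration of the central
hypergeometric distribution (vectorized per table); it agrees with
`scipy.stats.fisher_exact` to ~1e-14 and avoids scipy's per-call overhead on
the hundred-thousand-table oracle sweeps. The odds ratio is the conditional
MLE of Fisher's noncentral hypergeometric model, obtained by solving the
exponential-family score equation E_ψ[A] = a with Brent's method on log ψ
(xtol 1e-13); boundary tables map to 0/∞ and a single-point support to 1.
Bonferroni adjustment spans all (condition, cluster) tests within a cell line
(the family is configurable; the source is not fully explicit whether the
family was clusters only). The enrichment score is `clamp(log2 OR, −5, +5)`
when adjusted p < 0.01 and 0 otherwise, with 0/∞ odds ratios mapping to the
∓5 caps when significant. Clusters absent from both groups are skipped, not
scored 0.

## Condition geometry

Distances between conditions operate in a centered PCA of the RSS matrix
(20 components by default), deterministic up to the fixed
largest-loading-positive sign rule. Squared MMD uses the biased V-statistic
(identical samples give exactly 0 and the estimate is non-negative) with an
RBF kernel whose bandwidth is the median pairwise Euclidean distance over the
pooled groups; an unbiased U-statistic and a linear kernel are flags.
E-distance is 2·mean between-group squared Euclidean distance minus the two
within-group means; within-group means include the diagonal (all-pairs
V-statistic convention) so that identical point sets give exactly 0,
consistent with the MMD choice. KL divergence between compositions adds a
pseudocount of 1 to the counts before normalizing (natural log, direction
KL(first‖second)); the source's entropy call is direction- and
pseudocount-silent.

The reproducibility report groups samples by (treatment, induction, line) in
batches mode — yielding one distance per group for two batches, 24 for the
printed 12-treatment × 2-induction × 2-batch single-line design — or by
(treatment, induction) in lines mode, yielding C(8,2)=28 pairs per treatment
for 4 lines × 2 batches. One printed per-category count (326) in the source's
line-pair figure is not derivable from the stated design and is not
reproduced.

## Morphogen interactions

Condition centroids in the 20-PC space are centered on the control centroid
(no intercept in the decomposition: control-centering makes the origin the
"untreated" reference). For each (A, B, AB) triple, scipy's NNLS solves
min‖c_AB − a·c_A − b·c_B‖ with a, b ≥ 0; the reported non-additivity is the
Euclidean residual norm (squared norm by flag — the source does not specify
norm vs squared norm). The residual is zero exactly when the combination
centroid lies in the non-negative cone of the singles, and is invariant to
common rotations.

## Morphogen–regulon networks

The design matrix holds, per cell: a dose column per morphogen (ln(1+dose)
then min–max to [0,1]), a timing column per morphogen (exposure-start day, 0
untreated — the timing experiments vary a fixed-length pulse's start, so
start-day is the natural single encoding; midpoint/duration alternatives are
configurable), and caller-specified pairwise interaction columns (products of
scaled doses). Never-varying morphogens are dropped with a warning.

Each design column is regressed on all regulon activities with a random
forest (impurity importances; `max_features="sqrt"`); the link weight is the
importance × number of cells, so magnitudes are comparable across runs of
different size, and the full-scale retention threshold of 200 is meaningful
only at the original screen's scale — synthetic validation uses quantile
thresholds instead. Demultiplexing assigns interaction/timing column weights
to each parent morphogen with a kind flag, keeps the strongest connection per
(morphogen, regulon), and records the single raw source column per retained
link. Pearson correlations annotate each link against dose (concentration
series) and window start (timing series), optionally after seeded subsampling
to equal cells per condition. Non-linearity is tested with the Ramsey RESET
test (OLS on dose, augmentation with ŷ² and ŷ³, F-test of the augmentation;
statsmodels implementation) — an exactly linear fit returns p = 1 by
construction, and a collinear augmentation returns NaN with a warning.
Consensus regulons across repeated discovery runs drop TFs detected in fewer
than `min_fraction` (default 0.5 — an aggregation default, not a value from
the source) of all runs and keep targets supported by at least that fraction
of the detecting runs.

## Axis scoring

Dorsal/ventral modules grow from disjoint organizer seed sets (defaults:
PAX6, GLI3, BARHL1, GAS1, EMX1, WNT2B dorsal; NKX2-1, NKX2-2, SIX6, SIX3,
SHH, RAX, DLK1, FOXA2, SPON1, SULF1 ventral). Genes are treated as
observations: standardized across cells, PCA-reduced, joined into a
symmetrized kNN graph (k = 10); genes adjacent to a seed join that seed's
module, ties between sides resolved by seed-neighbor counts (dropped when
even). Module scores give `DV_score = dorsal − ventral`; the forebrain-axis
rank is the ordinal rank of that score, highest score (most anterodorsal) =
highest rank.

Label smoothening reassigns each cell to the region maximizing
Σ_neighbors J(i,j)·1[label_j = r], J the Jaccard overlap of the two cells'
kNN sets (k = 15); unlabeled cells receive the winning label, ties break by
raw vote count then the fixed anterior→posterior region order.

The AP model regresses the region ordinal (1–4) on a latent representation
with cross-validated elastic net (balanced subsample, default 5,000 cells per
class); predictions are continuous AP scores. The DV model thresholds
marker-based DV scores (default: 80th percentile of |score| — the original
absolute cutoff of 5 lives on its specific score scale and is not portable;
an absolute value is configurable), trains an elastic-net-penalized logistic
classifier on a seeded 80% subset, and scores cells on the link (linear
predictor) scale. The latent input here is the package's own RSS-PCA
embedding; the original workflow used a deep-model latent, which is out of
scope — this substitution is the one deliberate departure and means absolute
model coefficients are not transferable.

## The synthetic generator

The generator is the validation instrument, so its assumptions bound what
passing tests demonstrate. Per condition, cell-type logits are
`base_k + Σ_m β_{k,m}·dose_m + Σ γ_{k,(m1,m2)}·dose_m1·dose_m2 +
Σ_m τ_{k,m}·t_start`; types are drawn from the softmax. Expression is
negative binomial (dispersion 0.5, i.e. NB size 2 — mid-range overdispersion
for UMI data) around region profiles with disjoint marker blocks ≥ 4-fold
above a log-normal background; dorsal-region markers scale as
(0.2 + 1.6·dv) and ventral-region markers mirror-image in each cell's latent
dorsoventral coordinate dv ∈ [0,1] (dorsal-type cells draw dv uniformly from
[0.5,1], ventral from [0,0.5]). Hashtags follow a Poisson signal
(150 counts) over a 2% ambient background, with 5% doublets and 1% negatives
— rates in the range reported for hashed organoid pools. Regulon activities
are 0.2 + 0.6·d (sign +), 0.8 − 0.6·d (sign −), or the saturating quadratic
0.2 + 0.6·(2d − d²) for non-linear links, plus Gaussian noise (default SD
0.05), clipped to [0,1]. Per-condition cell numbers are free parameters (the
source reports only totals).

Deliberately not modeled: transcriptome-wide co-expression structure, batch
chemistry and ambient RNA in the expression matrix, doublet transcriptomes
(a doublet's expression comes from a single type; only its hashtags are
mixed), cell-cycle effects, and spatial structure. Consequently the
validation shows that each estimator recovers its target under the stated
generative model — faithful dose–response compositions, graded axes, NB
noise — not that it is robust to every artifact of real screens.

## Validation problem sizes and numerics

The oracle sweep enumerates all 164,176 2×2 tables with margins ≤ 30; the
test oracle maximizes the noncentral hypergeometric likelihood directly
(vectorized golden section plus Richardson-extrapolated parabolic vertex,
independent of the implementation's score-equation route) and agrees with the
implementation to < 1e-9 on |log OR| and < 1e-14 on p. Combination screens
for the non-additivity analysis use 7 conditions × 150 cells × 100 genes per
run, 100 seeded runs; the injected synergy (γ = 8 on a type no single
treatment promotes) attains the top residual in all runs. The link-recovery
screen uses 2 morphogens × 5 steps + control (~2,000 cells), 30 regulons and
6 true links, with the retention threshold at the 90th weight percentile —
with 60 candidate (morphogen, regulon) pairs the top decile has exactly the
capacity of the true link set, which is what makes precision and recall
simultaneously meaningful at that threshold. RESET power/size use n = 2,000,
noise SD 0.05, 100 replicates. Axis recovery uses an 1,600-cell two-region
gradient screen and 3,000–4,000-cell latent fixtures. These sizes were chosen
as the smallest at which the Monte-Carlo margins are comfortable.
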