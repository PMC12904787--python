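import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import morphoscreen as ms
from morphoscreen.axis import (
    AP_REGIONS,
    SeedMarkerSets,
    fb_axis_scores,
    predict_ap,
    predict_dv,
    seeded_gene_modules,
    smooth_region_labels,
    train_ap_model,
    train_dv_model,
)
from morphoscreen.io import lognorm_matrix


def _lognorm_frame(adata):
    return pd.DataFrame(
        np.asarray(lognorm_matrix(adata).todense()),
        index=adata.obs_names,
        columns=adata.var_names,
    )


@pytest.fixture(scope="module")
def forebrain_screen():
    """Two-region (dorsal/ventral) screen with graded DV marker genes."""
    atlas = ms.make_reference_atlas(2, 20, 150, seed=7)
    design = [ms.ConditionSpec("control"), ms.ConditionSpec("shh", ("SHH",), ("c3",))]
    adata, _, truth = ms.simulate_screen(design, atlas, 800, seed=8)
    adata = ms.lognormalize(adata)
    seeds = SeedMarkerSets(
        dorsal=atlas.marker_genes["region0"][:4],
        ventral=atlas.marker_genes["region1"][:4],
    )
    return atlas, adata, truth, seeds


class TestSeededModules:
    def test_correlated_gene_joins_seed_module(self, rng):
        # one gene tracks a "dorsal" program, another a "ventral" program
        n = 300
        prog_d = rng.normal(size=n)
        prog_v = rng.normal(size=n)
        cols = {
            "D1": prog_d + rng.normal(0, 0.1, n),
            "friend": prog_d + rng.normal(0, 0.1, n),
            "V1": prog_v + rng.normal(0, 0.1, n),
            "other": prog_v + rng.normal(0, 0.1, n),
            "noise": rng.normal(size=n),
        }
        expr = pd.DataFrame(cols)
        seeds = SeedMarkerSets(dorsal=["D1"], ventral=["V1"])
        dorsal, ventral = seeded_gene_modules(expr, seeds, k_neighbors=1, n_pcs=3)
        assert "friend" in dorsal
        assert "other" in ventral

    def test_seeds_always_in_their_own_module(self, forebrain_screen):
        atlas, adata, _, seeds = forebrain_screen
        dorsal, ventral = seeded_gene_modules(_lognorm_frame(adata), seeds)
        assert set(seeds.dorsal) <= set(dorsal)
        assert set(seeds.ventral) <= set(ventral)

    def test_recovers_latent_programs_with_high_jaccard(self, forebrain_screen):
        atlas, adata, _, seeds = forebrain_screen
        dorsal, ventral = seeded_gene_modules(_lognorm_frame(adata), seeds)
        truth_d = set(atlas.marker_genes["region0"])
        truth_v = set(atlas.marker_genes["region1"])
        jd = len(set(dorsal) & truth_d) / len(set(dorsal) | truth_d)
        jv = len(set(ventral) & truth_v) / len(set(ventral) | truth_v)
        assert jd >= 0.9 and jv >= 0.9

    def test_one_side_fully_absent_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            seeded_gene_modules(expr, SeedMarkerSets(dorsal=["a"], ventral=["zz"]), k_neighbors=2)

    def test_overlapping_seed_sets_rejected(self):
        with pytest.raises(ValueError):
            SeedMarkerSets(dorsal=["PAX6"], ventral=["PAX6"])


class TestFBAxisScores:
    def test_tracks_latent_dv_coordinate(self, forebrain_screen):
        atlas, adata, truth, seeds = forebrain_screen
        modules = seeded_gene_modules(_lognorm_frame(adata), seeds)
        scores = fb_axis_scores(adata, modules, seed=1)
        r = spearmanr(scores["FBaxis_score"], truth.dv_position).statistic
        assert r >= 0.9

    def test_rank_is_permutation_and_dv_identity_holds(self, forebrain_screen):
        _, adata, _, seeds = forebrain_screen
        modules = seeded_gene_modules(_lognorm_frame(adata), seeds)
        scores = fb_axis_scores(adata, modules, seed=1)
        assert sorted(scores["FBaxis_rank"]) == list(range(1, len(scores) + 1))
        np.testing.assert_allclose(
            scores["DV_score"], scores["dorsal_score"] - scores["ventral_score"]
        )

    def test_swapping_seed_sets_reverses_ranking(self, forebrain_screen):
        _, adata, _, seeds = forebrain_screen
        modules = seeded_gene_modules(_lognorm_frame(adata), seeds)
        fwd = fb_axis_scores(adata, modules, seed=1)
        rev = fb_axis_scores(adata, (modules[1], modules[0]), seed=1)
        r = spearmanr(fwd["FBaxis_rank"], rev["FBaxis_rank"]).statistic
        assert r <= -0.98


class TestSmoothLabels:
    @staticmethod
    def _clustered(n_per=40, seed=0):
        rng = np.random.default_rng(seed)
        latent, labels = [], []
        for i, r in enumerate(AP_REGIONS):
            latent.append(rng.normal(loc=4 * i, scale=0.3, size=(n_per, 2)))
            labels += [r] * n_per
        return np.vstack(latent), np.array(labels, dtype=object)

    def test_homogeneous_neighborhood_keeps_label(self):
        latent, labels = self._clustered()
        out = smooth_region_labels(latent, labels, k_neighbors=10)
        assert (out == labels).all()

    def test_mislabeled_cell_inside_foreign_cluster_reassigned(self):
        latent, labels = self._clustered()
        labels[0] = "rhombencephalon"  # sits inside the telencephalon cluster
        out = smooth_region_labels(latent, labels, k_neighbors=10)
        assert out[0] == "telencephalon"

    def test_none_cells_receive_winning_label(self):
        latent, labels = self._clustered()
        labels[5] = None
        out = smooth_region_labels(latent, labels, k_neighbors=10)
        assert out[5] == "telencephalon"

    def test_all_identical_labels_are_fixed_point(self):
        rng = np.random.default_rng(2)
        latent = rng.normal(size=(50, 2))
        labels = np.array(["diencephalon"] * 50, dtype=object)
        out = smooth_region_labels(latent, labels, k_neighbors=8)
        assert (out == labels).all()

    def test_applied_twice_is_contractive(self):
        latent, labels = self._clustered(seed=3)
        rng = np.random.default_rng(4)
        noisy = labels.copy()
        flip = rng.choice(len(labels), 15, replace=False)
        noisy[flip] = rng.choice(AP_REGIONS, 15)
        once = smooth_region_labels(latent, noisy, k_neighbors=10)
        twice = smooth_region_labels(latent, once, k_neighbors=10)
        assert (twice != once).sum() <= (once != noisy).sum()

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            smooth_region_labels(np.zeros((5, 2)), np.array(["x"] * 5), k_neighbors=5)


class TestAPModel:
    @staticmethod
    def _latent(n, seed=0, noise=0.3):
        rng = np.random.default_rng(seed)
        ords = rng.integers(1, 5, n)
        latent = np.column_stack([ords + rng.normal(0, noise, n), rng.normal(0, 1, (n, 4))])
        labels = np.array(AP_REGIONS, dtype=object)[ords - 1]
        return latent, labels, ords

    def test_heldout_predictions_track_ordinal(self):
        latent, labels, ords = self._latent(3000)
        model = train_ap_model(latent[:2400], labels[:2400], seed=0)
        pred = predict_ap(model, latent[2400:])
        assert spearmanr(pred, ords[2400:]).statistic >= 0.95

    def test_region_centroid_predictions_increase_with_ordinal(self):
        latent, labels, ords = self._latent(2000, seed=1)
        model = train_ap_model(latent, labels, seed=1)
        centroids = [latent[ords == v].mean(axis=0) for v in (1, 2, 3, 4)]
        pred = predict_ap(model, np.vstack(centroids))
        assert (np.diff(pred) > 0).all()

    def test_permuted_labels_have_no_predictive_power(self):
        rng = np.random.default_rng(2)
        latent, labels, ords = self._latent(2000, seed=2)
        perm = rng.permutation(labels)
        model = train_ap_model(latent[:1600], perm[:1600], seed=2)
        pred = predict_ap(model, latent[1600:])
        r = spearmanr(pred, ords[1600:]).statistic
        assert np.isnan(r) or abs(r) < 0.2

    def test_zero_variance_latent_rejected(self):
        with pytest.raises(ValueError):
            train_ap_model(np.zeros((100, 3)), np.array(["telencephalon"] * 100))


class TestDVModel:
    def test_separable_latent_separates_perfectly(self):
        rng = np.random.default_rng(3)
        n = 600
        dorsal = rng.uniform(size=n) < 0.5
        latent = np.column_stack([np.where(dorsal, 2.0, -2.0) + rng.normal(0, 0.2, n),
                                  rng.normal(0, 1, (n, 3))])
        marker = np.where(dorsal, 8.0, -8.0) + rng.normal(0, 0.5, n)
        model = train_dv_model(latent, marker, threshold=5.0, seed=0)
        link = predict_dv(model, latent)
        assert (link[dorsal] > 0).all() and (link[~dorsal] < 0).all()

    def test_link_score_monotone_in_latent_gradient(self):
        rng = np.random.default_rng(4)
        n = 2000
        dv = rng.uniform(0, 1, n)
        latent = np.column_stack([4 * dv - 2 + rng.normal(0, 0.2, n), rng.normal(0, 1, (n, 3))])
        marker = (dv - 0.5) * 10 + rng.normal(0, 0.5, n)
        model = train_dv_model(latent, marker, seed=0)
        link = predict_dv(model, latent)
        assert spearmanr(link, dv).statistic >= 0.9

    def test_threshold_above_max_score_rejected(self):
        rng = np.random.default_rng(5)
        latent = rng.normal(size=(100, 3))
        marker = rng.normal(0, 1, 100)
        with pytest.raises(ValueError, match="threshold"):
            train_dv_model(latent, marker, threshold=100.0)
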