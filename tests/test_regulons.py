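import itertools

import numpy as np
import pandas as pd
import pytest

import morphoscreen as ms
from morphoscreen.regulons import MorphogenDesign


def _meta(n=200, morphogens=("SHH",), seed=0, doses=None, t_start=None):
    rng = np.random.default_rng(seed)
    data = {}
    for m in morphogens:
        data[f"dose_{m}"] = doses if doses is not None else rng.choice(
            [0.0, 0.0625, 0.125, 0.25, 0.5, 1.0], size=n
        )
    data["t_start"] = t_start if t_start is not None else rng.choice([0.0, 3.0, 9.0], size=n)
    data["condition"] = [f"cond{i % 8}" for i in range(n)]
    return pd.DataFrame(data, index=[f"c{i}" for i in range(n)])


class TestBuildDesign:
    def test_untreated_cells_have_all_zero_rows(self):
        meta = _meta(n=20, doses=np.r_[np.zeros(10), np.full(10, 0.5)],
                     t_start=np.r_[np.zeros(10), np.full(10, 6.0)])
        design = ms.build_design(meta)
        np.testing.assert_allclose(design.matrix.iloc[:10].values, 0.0)

    def test_top_step_scales_to_one(self):
        meta = _meta(n=10, doses=np.r_[np.zeros(5), np.full(5, 1.0)])
        design = ms.build_design(meta, include_timing=False)
        assert design.matrix["SHH"].max() == pytest.approx(1.0)
        assert design.matrix["SHH"].min() == 0.0

    def test_39_pseudomorphogens_from_8_morphogens_and_23_interactions(self):
        # 8 dose + 8 timing + 23 interaction columns
        morphs = [f"M{i}" for i in range(8)]
        rng = np.random.default_rng(1)
        meta = _meta(n=100, morphogens=morphs, seed=1)
        for m in morphs:  # ensure each morphogen varies
            meta[f"dose_{m}"] = rng.choice([0.0, 0.5, 1.0], size=100)
        pairs = list(itertools.combinations(morphs, 2))[:23]
        design = ms.build_design(meta, interactions=pairs)
        assert design.matrix.shape[1] == 39
        kinds = pd.Series([k for _, k in design.columns.values()])
        assert (kinds == "dose").sum() == 8
        assert (kinds == "time").sum() == 8
        assert (kinds == "interaction").sum() == 23

    def test_interaction_columns_are_products_of_parents(self):
        meta = _meta(n=50, morphogens=("A", "B"), seed=2)
        design = ms.build_design(meta, interactions=[("A", "B")], include_timing=False)
        np.testing.assert_allclose(
            design.matrix["A*B"], design.matrix["A"] * design.matrix["B"]
        )

    def test_constant_morphogen_dropped(self):
        meta = _meta(n=20, doses=np.full(20, 0.5))
        design = ms.build_design(meta, include_timing=False)
        assert "SHH" not in design.matrix.columns


class TestLinkRegulons:
    def test_noiseless_monotone_link_gets_top_weight(self):
        meta = _meta(n=400, seed=3)
        act = ms.simulate_regulon_activities(
            meta, [ms.TrueLink("SHH", "R0", +1)], noise_sd=0.0, seed=3, n_regulons=10
        )
        design = ms.build_design(meta, include_timing=False)
        raw = ms.link_regulons(act, design, n_estimators=50, seed=0)
        best = raw.loc[raw.weight.idxmax()]
        assert (best["column"], best["regulon"]) == ("SHH", "R0")

    def test_permuted_activities_have_no_strong_weights(self):
        rng = np.random.default_rng(4)
        meta = _meta(n=500, seed=4)
        act = ms.simulate_regulon_activities(
            meta, [ms.TrueLink("SHH", "R0", +1)], noise_sd=0.05, seed=4, n_regulons=10
        )
        design = ms.build_design(meta, include_timing=False)
        true_raw = ms.link_regulons(act, design, n_estimators=50, seed=0)
        perm = act.sample(frac=1.0, random_state=5).reset_index(drop=True)
        perm.index = act.index
        perm_raw = ms.link_regulons(perm, design, n_estimators=50, seed=0)
        # permutation breaks the link: its top weight falls far below the
        # genuine link weight
        assert perm_raw.weight.max() < 0.5 * true_raw.weight.max()

    def test_empty_activity_rejected(self):
        meta = _meta(n=20)
        design = ms.build_design(meta)
        with pytest.raises(ValueError):
            ms.link_regulons(pd.DataFrame(index=meta.index), design)


class TestDemultiplexLinks:
    @staticmethod
    def _design_stub():
        return MorphogenDesign(
            pd.DataFrame(),
            {
                "m1": (("m1",), "dose"),
                "m2": (("m2",), "dose"),
                "m1:time": (("m1",), "time"),
                "m1*m2": (("m1", "m2"), "interaction"),
            },
        )

    def test_interaction_link_flagged_for_both_parents(self):
        raw = pd.DataFrame([{"column": "m1*m2", "regulon": "R", "weight": 400.0}])
        links = ms.demultiplex_links(raw, self._design_stub())
        assert set(links["morphogen"]) == {"m1", "m2"}
        assert (links["kind"] == "interaction").all()

    def test_strongest_connection_wins(self):
        raw = pd.DataFrame([
            {"column": "m1", "regulon": "R", "weight": 300.0},
            {"column": "m1:time", "regulon": "R", "weight": 250.0},
        ])
        links = ms.demultiplex_links(raw, self._design_stub())
        assert len(links) == 1
        assert links.iloc[0]["weight"] == 300.0
        assert links.iloc[0]["kind"] == "dose"
        assert links.iloc[0]["source_column"] == "m1"

    def test_threshold_filters_everything_when_weights_low(self):
        raw = pd.DataFrame([{"column": "m1", "regulon": "R", "weight": 10.0}])
        assert ms.demultiplex_links(raw, self._design_stub()).empty


class TestAnnotateCorrelations:
    def test_noiseless_increasing_activity_has_unit_concentration_correlation(self):
        meta = _meta(n=100, seed=5)
        meta["series"] = "concentration"
        act = ms.simulate_regulon_activities(
            meta, [ms.TrueLink("SHH", "R0", +1)], noise_sd=0.0, seed=5, n_regulons=3
        )
        links = pd.DataFrame([{"morphogen": "SHH", "regulon": "R0", "weight": 500.0}])
        out = ms.annotate_correlations(links, act, meta)
        assert out["r_concentration"].iloc[0] == pytest.approx(1.0)

    def test_timing_independent_activity_has_small_timing_correlation(self):
        rng = np.random.default_rng(6)
        meta = _meta(n=2000, seed=6)
        meta["series"] = "timing"
        act = pd.DataFrame({"R0": rng.uniform(0, 1, 2000)}, index=meta.index)
        links = pd.DataFrame([{"morphogen": "SHH", "regulon": "R0", "weight": 500.0}])
        out = ms.annotate_correlations(links, act, meta)
        assert abs(out["r_timing"].iloc[0]) < 0.1

    def test_constant_activity_gives_nan(self):
        meta = _meta(n=50, seed=7)
        meta["series"] = "concentration"
        act = pd.DataFrame({"R0": np.full(50, 0.5)}, index=meta.index)
        links = pd.DataFrame([{"morphogen": "SHH", "regulon": "R0", "weight": 500.0}])
        out = ms.annotate_correlations(links, act, meta)
        assert np.isnan(out["r_concentration"].iloc[0])


class TestResetTest:
    def test_exactly_linear_activity_is_not_rejected(self):
        dose = np.tile([0.0, 0.25, 0.5, 1.0], 25)
        p = ms.reset_test(0.2 + 0.6 * dose, dose)
        assert p > 0.99

    def test_quadratic_activity_is_rejected(self):
        rng = np.random.default_rng(8)
        dose = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], 500)
        act = 4 * dose * (1 - dose) + rng.normal(0, 0.05, 500)
        assert ms.reset_test(act, dose) < 1e-6

    def test_f_statistic_matches_restricted_rss_formula(self):
        # 12-point toy set: build the RESET F by hand from restricted and
        # unrestricted residual sums of squares
        rng = np.random.default_rng(9)
        dose = np.linspace(0, 1, 12)
        act = 0.3 + 0.5 * dose**2 + rng.normal(0, 0.02, 12)
        X = np.column_stack([np.ones(12), dose])
        beta = np.linalg.lstsq(X, act, rcond=None)[0]
        yhat = X @ beta
        rss_r = np.sum((act - yhat) ** 2)
        Xu = np.column_stack([X, yhat**2, yhat**3])
        beta_u = np.linalg.lstsq(Xu, act, rcond=None)[0]
        rss_u = np.sum((act - Xu @ beta_u) ** 2)
        q, dfu = 2, 12 - 4
        f_oracle = (rss_r - rss_u) / q / (rss_u / dfu)
        from scipy.stats import f as fdist
        p_oracle = fdist.sf(f_oracle, q, dfu)
        assert ms.reset_test(act, dose) == pytest.approx(p_oracle, rel=1e-8)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            ms.reset_test(np.ones(5), np.arange(5))
        with pytest.raises(ValueError):
            ms.reset_test(np.arange(20.0), np.ones(20))


class TestConsensus:
    def test_identical_runs_are_identity(self):
        run = {"TF1": ["a", "b"], "TF2": ["c"]}
        cons, support = ms.consensus_regulons([run, run, run])
        assert cons == {"TF1": ["a", "b"], "TF2": ["c"]}
        assert (support["support"] == 1.0).all()

    def test_low_support_target_excluded(self):
        runs = [{"TF": ["a", "b"]}] * 2 + [{"TF": ["a"]}] * 3
        cons, _ = ms.consensus_regulons(runs, min_fraction=0.5)
        assert cons["TF"] == ["a"]  # b in 2/5 runs < 0.5

    def test_rare_tf_dropped(self):
        runs = [{"TF1": ["a"]}] * 4 + [{"TF1": ["a"], "TF2": ["z"]}]
        cons, _ = ms.consensus_regulons(runs, min_fraction=0.5)
        assert "TF2" not in cons

    def test_recovers_ground_truth_from_noisy_runs(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(200)]
        truth = {f"TF{k}": sorted(rng.choice(genes, 20, replace=False)) for k in range(5)}
        runs = []
        for _ in range(10):
            run = {}
            for tf, targets in truth.items():
                noise = list(rng.choice(genes, int(0.2 * len(targets)), replace=False))
                run[tf] = sorted(set(targets) | set(noise))
            runs.append(run)
        cons, _ = ms.consensus_regulons(runs, min_fraction=0.5)
        tp = sum(len(set(cons[tf]) & set(truth[tf])) for tf in truth)
        found = sum(len(cons[tf]) for tf in truth)
        expected = sum(len(truth[tf]) for tf in truth)
        assert tp / found >= 0.95  # precision
        assert tp / expected >= 0.95  # recall

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ms.consensus_regulons([])
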