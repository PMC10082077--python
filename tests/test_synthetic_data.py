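import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diauxflux import fba_engine as fe
from diauxflux import synthetic_data as sd


class TestToyModelPair:
    def test_seed_determinism(self):
        a = sd.make_toy_model_pair(seed=4)
        b = sd.make_toy_model_pair(seed=4)
        assert np.allclose(a[0].S, b[0].S)
        assert a[0].reaction_ids == b[0].reaction_ids
        assert a[1].rules == b[1].rules
        assert a[2].rules == b[2].rules
        assert a[3].affected_genes == b[3].affected_genes

    def test_affected_knockout_discriminates_variants(self, toy_pair):
        model, r1, r2, truth = toy_pair
        for gene in truth.affected_genes:
            g_a = fe.phase_growth(model, r1, gene, "post")
            g_b = fe.phase_growth(model, r2, gene, "post")
            assert abs(g_b - g_a) > 0

    def test_silent_gene_has_exactly_zero_difference(self, toy_pair):
        model, r1, r2, truth = toy_pair
        ruled = {r.gene for r in r1.rules} | {r.gene for r in r2.rules}
        silent = [g for g in model.regulator_genes if g not in ruled]
        assert silent, "fixture needs at least one rule-free regulator"
        g_a = fe.phase_growth(model, r1, silent[0], "post")
        g_b = fe.phase_growth(model, r2, silent[0], "post")
        assert g_b - g_a == 0.0

    def test_wild_type_viable_in_both_phases(self, toy_pair):
        model, r1, r2, _ = toy_pair
        for rules in (r1, r2):
            for phase in ("pre", "post"):
                assert fe.phase_growth(model, rules, None, phase) > 0

    def test_rule_sets_differ(self, toy_pair):
        _, r1, r2, _ = toy_pair
        assert set(r1.rules) != set(r2.rules)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            sd.make_toy_model_pair(n_internal_mets=3)
        with pytest.raises(ValueError):
            sd.make_toy_model_pair(n_regulator_genes=2)


class TestGrowthCurves:
    def test_noiseless_pre_shift_slope(self):
        curve = sd.simulate_growth_curve(pre_rate=0.4, post_rate=0.1,
                                         shift_time=12.0, od0=0.01,
                                         noise_sd=0.0)
        pre = curve.time < 12.0
        slopes = np.diff(np.log(curve.od[pre])) / np.diff(curve.time[pre])
        assert np.allclose(slopes, 0.4, atol=1e-9)

    def test_equal_rates_no_lag_is_single_exponential(self):
        curve = sd.simulate_growth_curve(pre_rate=0.3, post_rate=0.3,
                                         shift_time=10.0, lag=0.0, od0=0.01,
                                         horizon=15.0, noise_sd=0.0)
        slopes = np.diff(np.log(curve.od)) / np.diff(curve.time)
        assert np.allclose(slopes, 0.3, atol=1e-9)

    def test_seed_determinism(self):
        a = sd.simulate_growth_curve(noise_sd=0.01, seed=9)
        b = sd.simulate_growth_curve(noise_sd=0.01, seed=9)
        assert np.array_equal(a.od, b.od)

    def test_clipped_to_instrument_range(self):
        curve = sd.simulate_growth_curve(pre_rate=0.6, shift_time=20.0,
                                         od0=0.05, noise_sd=0.0)
        assert curve.od.max() <= 2.0
        assert curve.od.min() >= 0.0

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            sd.simulate_growth_curve(pre_rate=0.0)


class TestPeakTables:
    def test_seed_determinism(self):
        design = sd.SimDesign(n_features=20, seed=5)
        a, _ = sd.simulate_peak_table(design)
        b, _ = sd.simulate_peak_table(design)
        pd.testing.assert_frame_equal(a.intensities, b.intensities)
        pd.testing.assert_frame_equal(a.sample_meta, b.sample_meta)

    def test_planted_fold_change_recovered(self):
        design = sd.SimDesign(n_strains=1, replicates_per_condition=30,
                              n_batches=1, n_features=10, missing_rate=0.0,
                              seed=3)
        table, truth = sd.simulate_peak_table(
            design, effects=[{"feature": "F0001", "log2fc": 1.0, "phase": "post"}],
            drift_amplitude=0.0)
        assert truth.true_diff_features == {"F0001": 1.0}
        meta = table.sample_meta
        study = meta[meta["class"] == "sample"]
        post = study.index[study["phase"] == "post"]
        pre = study.index[study["phase"] == "pre"]
        log_ratio = (np.log2(table.intensities.loc["F0001", post]).mean()
                     - np.log2(table.intensities.loc["F0001", pre]).mean())
        # geometric-mean ratio approx 2 within a generous CI at n=30
        se = 0.3 * np.sqrt(2 / 30)
        assert abs(log_ratio - 1.0) < 4 * se

    def test_null_features_calibrated(self):
        # no planted effects: per-feature two-sample t-tests across phases
        # reject at roughly the nominal rate
        design = sd.SimDesign(n_strains=1, replicates_per_condition=10,
                              n_batches=1, n_features=400, missing_rate=0.0,
                              seed=11)
        table, _ = sd.simulate_peak_table(design, drift_amplitude=0.0)
        meta = table.sample_meta
        study = meta[meta["class"] == "sample"]
        post = study.index[study["phase"] == "post"]
        pre = study.index[study["phase"] == "pre"]
        X = np.log2(table.intensities.to_numpy())
        a = X[:, [table.intensities.columns.get_loc(c) for c in post]]
        b = X[:, [table.intensities.columns.get_loc(c) for c in pre]]
        p = stats.ttest_ind(a, b, axis=1).pvalue
        rate = (p < 0.05).mean()
        # binomial 99.9% band around 0.05 at n=400
        assert 0.05 - 3.3 * np.sqrt(0.05 * 0.95 / 400) < rate < \
               0.05 + 3.3 * np.sqrt(0.05 * 0.95 / 400)

    def test_qc_tighter_than_samples_without_drift(self):
        design = sd.SimDesign(n_strains=2, replicates_per_condition=6,
                              n_batches=1, n_features=30, missing_rate=0.0,
                              seed=2)
        table, _ = sd.simulate_peak_table(design, drift_amplitude=0.0)
        meta = table.sample_meta
        qc = table.intensities[meta.index[meta["class"] == "QC"]]
        study = table.intensities[meta.index[meta["class"] == "sample"]]
        qc_cv = (qc.std(axis=1) / qc.mean(axis=1)).median()
        s_cv = (study.std(axis=1) / study.mean(axis=1)).median()
        assert qc_cv < s_cv

    def test_blanks_carry_noise_floor_only(self, small_study):
        table, _ = small_study
        meta = table.sample_meta
        blanks = table.intensities[meta.index[meta["class"] == "blank"]]
        study = table.intensities[meta.index[meta["class"] == "sample"]]
        assert np.all(blanks.mean(axis=1) < study.replace(0, np.nan).mean(axis=1))

    def test_missingness_rate(self):
        design = sd.SimDesign(n_features=200, missing_rate=0.1, seed=8)
        table, _ = sd.simulate_peak_table(design)
        meta = table.sample_meta
        study = table.intensities[meta.index[meta["class"] == "sample"]]
        frac = (study.to_numpy() == 0).mean()
        assert 0.07 < frac < 0.13

    def test_unknown_effect_feature_rejected(self):
        design = sd.SimDesign(n_features=5, seed=0)
        with pytest.raises(ValueError):
            sd.simulate_peak_table(design, effects=[{"feature": "F9999",
                                                     "log2fc": 1.0}])

    def test_zero_fold_change_rejected(self):
        design = sd.SimDesign(n_features=5, seed=0)
        with pytest.raises(ValueError):
            sd.simulate_peak_table(design, effects=[{"feature": "F0001",
                                                     "log2fc": 0.0}])

    def test_paired_noise_makes_null_strains_identical(self):
        design = sd.SimDesign(n_strains=3, replicates_per_condition=4,
                              n_batches=1, n_features=15, missing_rate=0.0,
                              seed=6)
        table, _ = sd.simulate_peak_table(
            design, effects=[{"feature": "F0001", "log2fc": 2.0,
                              "strain": "KO1", "phase": "post"}],
            drift_amplitude=0.0, paired_noise=True)
        meta = table.sample_meta
        for ph in ("pre", "post"):
            wt = sorted(meta.index[(meta["strain"] == "WT") & (meta["phase"] == ph)])
            ko2 = sorted(meta.index[(meta["strain"] == "KO2") & (meta["phase"] == ph)])
            assert np.array_equal(table.intensities[wt].to_numpy(),
                                  table.intensities[ko2].to_numpy())


class TestKnowledgeGraphs:
    def test_seed_determinism(self):
        a, _ = sd.make_knowledge_graph(seed=3)
        b, _ = sd.make_knowledge_graph(seed=3)
        assert set(a.edges) == set(b.edges)
        assert dict(a.nodes(data="type")) == dict(b.nodes(data="type"))

    def test_connected_and_typed(self):
        g, _ = sd.make_knowledge_graph(seed=1)
        assert nx.is_connected(g)
        types = set(nx.get_node_attributes(g, "type").values())
        assert types == {"pathway", "reaction", "compound"}

    def test_every_compound_reachable_from_a_pathway(self):
        g, _ = sd.make_knowledge_graph(seed=2)
        pathways = [n for n, t in g.nodes(data="type") if t == "pathway"]
        reach = set()
        for p in pathways:
            reach |= nx.node_connected_component(g, p)
        compounds = {n for n, t in g.nodes(data="type") if t == "compound"}
        assert compounds <= reach

    def test_planted_pathway_compounds_disjoint_from_decoys(self):
        g, truth = sd.make_knowledge_graph(seed=5)
        planted = sorted(truth.enriched_pathways)[0]
        planted_set = set(truth.pathway_compounds[planted])
        assert len(planted_set) >= 3
        for p, members in truth.pathway_compounds.items():
            if p not in truth.enriched_pathways:
                assert planted_set.isdisjoint(members)

    def test_tsv_round_trip(self, tmp_path):
        g, _ = sd.make_knowledge_graph(seed=7)
        sd.write_graph_tsv(g, tmp_path / "e.tsv", tmp_path / "n.tsv")
        back = sd.read_graph_tsv(tmp_path / "e.tsv", tmp_path / "n.tsv")
        assert set(back.edges) == set(g.edges)
        assert dict(back.nodes(data="type")) == dict(g.nodes(data="type"))

    def test_requires_two_pathways(self):
        with pytest.raises(ValueError):
            sd.make_knowledge_graph(n_pathways=1)
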