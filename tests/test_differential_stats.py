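import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import fcluster

from conftest import make_peak_table
from diauxflux import differential_stats as ds
from diauxflux import synthetic_data as sd


def phase_table(n_features, effects=None, reps=6, seed=0, strains=1, batches=2):
    design = sd.SimDesign(n_strains=strains, replicates_per_condition=reps,
                          n_batches=batches, n_features=n_features,
                          missing_rate=0.0, seed=seed)
    return sd.simulate_peak_table(design, effects=effects, drift_amplitude=0.0)


class TestFitLinearModel:
    def test_recovers_planted_phase_effect(self):
        effects = [{"feature": f"F{i + 1:04d}", "log2fc": 1.0, "phase": "post"}
                   for i in range(50)]
        table, _ = phase_table(60, effects=effects, seed=1)
        diff = ds.fit_linear_model(table, contrast="phase", covariates=("batch",))
        hits = diff.table.iloc[:50]
        assert (hits["p_raw"] < 0.1).mean() >= 0.95
        assert hits["coef_log2"].median() == pytest.approx(1.0, abs=0.15)
        assert np.all(hits["fold_change"] > 0)

    def test_null_pvalues_roughly_uniform(self):
        table, _ = phase_table(1000, seed=2)
        diff = ds.fit_linear_model(table, contrast="phase", covariates=("batch",))
        ks = stats.kstest(diff.table["p_raw"], "uniform")
        assert ks.pvalue > 0.01

    def test_batch_effect_absorbed_by_covariate(self):
        # heavy batch effects, no phase effect: contrast p stays uniform
        design = sd.SimDesign(n_strains=1, replicates_per_condition=6,
                              n_batches=2, n_features=800, missing_rate=0.0,
                              seed=3)
        table, _ = sd.simulate_peak_table(design, batch_sd_log2=1.5,
                                          drift_amplitude=0.0)
        diff = ds.fit_linear_model(table, contrast="phase", covariates=("batch",))
        ks = stats.kstest(diff.table["p_raw"], "uniform")
        assert ks.pvalue > 0.01

    def test_confounded_design_rejected(self):
        X = np.abs(np.random.default_rng(0).lognormal(5, 1, size=(5, 8)))
        table = make_peak_table(
            X, phases=["pre"] * 4 + ["post"] * 4,
            batches=["B1"] * 4 + ["B2"] * 4)
        with pytest.raises(ValueError, match="confounded"):
            ds.fit_linear_model(table, contrast="phase", covariates=("batch",))

    def test_strain_contrast_subsets_to_reference_pair(self):
        design = sd.SimDesign(n_strains=3, replicates_per_condition=4,
                              n_batches=1, n_features=20, missing_rate=0.0,
                              seed=4)
        table, _ = sd.simulate_peak_table(
            design, effects=[{"feature": "F0001", "log2fc": 2.0,
                              "strain": "KO1", "phase": "post"}],
            drift_amplitude=0.0)
        diff = ds.fit_linear_model(table, contrast="strain", strain="KO1",
                                   phase="post", covariates=())
        assert diff.table.loc["F0001", "p_raw"] < 0.01
        assert diff.table.loc["F0001", "coef_log2"] == pytest.approx(2.0, abs=0.6)

    def test_moderation_agrees_as_replicates_grow(self):
        # per-feature variances concentrate at rate sqrt(2/df), so the
        # moderated and raw p-values converge as replication grows
        medians = []
        for reps in (6, 50):
            effects = [{"feature": "F0001", "log2fc": 0.5, "phase": "post"}]
            table, _ = phase_table(300, effects=effects, reps=reps,
                                   batches=1, seed=5)
            diff = ds.fit_linear_model(table, contrast="phase", covariates=(),
                                       moderate=True)
            delta = (diff.table["p_raw"] - diff.table["p_moderated"]).abs()
            medians.append(delta.median())
        assert medians[1] < medians[0]
        assert medians[1] < 0.02

    def test_moderated_pvalues_valid(self):
        table, _ = phase_table(200, seed=6)
        diff = ds.fit_linear_model(table, contrast="phase",
                                   covariates=("batch",), moderate=True)
        p = diff.table["p_moderated"]
        assert p.between(0, 1).all()


class TestVolcanoClassify:
    def _diff(self, rows):
        table = pd.DataFrame(rows, columns=["coef_log2", "p_raw"])
        table.index = [f"F{i}" for i in range(len(rows))]
        table["fold_change"] = 2.0 ** table["coef_log2"].abs()
        table["sign"] = np.sign(table["coef_log2"])
        return ds.DiffResult(table=table, contrast="phase", covariates=())

    def test_flags_only_joint_exceedance(self):
        rows = [(1.0, 0.05), (0.1, 0.05), (1.0, 0.5), (2.0, 0.01),
                (-1.5, 0.02), (0.2, 0.9), (1.2, 0.09), (0.05, 0.001),
                (3.0, 0.099), (0.9, 0.15)]
        flagged = ds.volcano_classify(self._diff(rows))
        assert flagged == {"F0", "F3", "F4", "F6", "F8"}

    def test_boundaries_are_strict(self):
        rows = [(np.log2(1.5), 0.05), (1.0, 0.1)]
        flagged = ds.volcano_classify(self._diff(rows))
        assert flagged == set()


class TestCorrelationProfiles:
    def test_duplicated_group_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        X = rng.lognormal(5, 1, size=(20, 8))
        X[:, 4:] = X[:, :4]  # strain B duplicates strain A
        table = make_peak_table(X, strains=["A"] * 4 + ["B"] * 4)
        prof = ds.correlation_profiles(table, group_by=("strain",))
        assert prof.correlations.loc["A", "B"] == pytest.approx(1.0)
        assert prof.group_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profile(self):
        rng = np.random.default_rng(1)
        a = rng.normal(100, 30, size=20)
        b = 200 - a  # mean-centered mirror
        X = np.column_stack([a, a, b, b])
        table = make_peak_table(X, strains=["A", "A", "B", "B"])
        prof = ds.correlation_profiles(table, group_by=("strain",))
        assert prof.correlations.loc["A", "B"] == pytest.approx(-1.0)

    def test_two_cluster_structure_recovered(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(5, 1, size=30)
        shift = rng.lognormal(5, 1, size=30)
        cols, strains = [], []
        for s, profile in [("A", base), ("B", base), ("C", shift), ("D", shift)]:
            for r in range(3):
                cols.append(profile * np.exp(rng.normal(0, 0.05, 30)))
                strains.append(s)
        table = make_peak_table(np.column_stack(cols), strains=strains)
        prof = ds.correlation_profiles(table, group_by=("strain",))
        labels = fcluster(prof.group_linkage, 2, criterion="maxclust")
        groups = dict(zip(prof.group_labels, labels))
        assert groups["A"] == groups["B"]
        assert groups["C"] == groups["D"]
        assert groups["A"] != groups["C"]

    def test_requires_two_groups(self):
        X = np.ones((5, 4)) * 10
        table = make_peak_table(X)
        with pytest.raises(ValueError):
            ds.correlation_profiles(table, group_by=("strain",))


class TestOplsDa:
    def _separable(self, n=30, p=50, shift=3.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, size=(n, p))
        y = np.array(["pre"] * (n // 2) + ["post"] * (n // 2))
        X[y == "post"] += shift
        return X, y

    def test_score_orthogonality(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 20))
        y = np.array(["a", "b"] * 20)
        model = ds.fit_opls_da(X, y, n_orthogonal=3)
        for k in range(model.T_orth.shape[1]):
            assert abs(model.t_pred @ model.T_orth[:, k]) <= 1e-8

    def test_separable_classes_classified_perfectly(self):
        X, y = self._separable()
        model = ds.fit_opls_da(X, y, n_orthogonal=1)
        assert (model.predict(X) == y).mean() == 1.0

    def test_zero_orthogonal_equals_pls1(self):
        from sklearn.cross_decomposition import PLSRegression
        X, y = self._separable(n=24, p=10, shift=1.0, seed=4)
        model = ds.fit_opls_da(X, y, n_orthogonal=0)
        yy = np.where(y == model.classes[1], 1.0, -1.0)
        pls = PLSRegression(n_components=1, scale=False).fit(X - X.mean(0), yy - yy.mean())
        t_sk = pls.x_scores_[:, 0]
        rho = np.corrcoef(model.t_pred, t_sk)[0, 1]
        assert abs(rho) > 1 - 1e-10

    def test_permuted_labels_give_chance_level_mean(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 10))
        y = np.array(["a"] * 100 + ["b"] * 100)
        X[y == "b"] += 3.0
        accs = []
        for _ in range(20):
            yp = rng.permutation(y)
            m = ds.fit_opls_da(X, yp, n_orthogonal=1)
            accs.append((m.predict(X) == yp).mean())
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_rejects_rank_deficient_request(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(8, 3))
        y = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError):
            ds.fit_opls_da(X, y, n_orthogonal=3)

    def test_requires_three_per_class(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 4))
        y = np.array(["a", "a", "a", "b", "b"])
        with pytest.raises(ValueError):
            ds.fit_opls_da(X, y)


class TestSelectDiscriminatingFeatures:
    def _setup(self):
        rng = np.random.default_rng(8)
        n, p = 40, 12
        X = rng.normal(size=(n, p))
        y = np.array(["pre"] * 20 + ["post"] * 20)
        X[y == "post", 0] += 4.0   # strongest phase feature
        X[y == "post", 1] += 1.0
        fids = [f"F{i}" for i in range(p)]
        model = ds.fit_opls_da(X, y, n_orthogonal=1)
        pvals = np.full(p, 0.5)
        pvals[:3] = [1e-6, 1e-3, 0.05]  # F2 sits exactly on the boundary
        diff = ds.DiffResult(table=pd.DataFrame({
            "coef_log2": np.zeros(p), "sign": np.zeros(p),
            "fold_change": np.ones(p), "p_raw": pvals}, index=fids),
            contrast="phase", covariates=())
        return model, diff, fids

    def test_strongest_feature_ranks_first(self):
        model, diff, fids = self._setup()
        sel = ds.select_discriminating_features(model, diff, fids, top_n=2)
        assert sel[0] == "F0"

    def test_boundary_pvalue_excluded(self):
        model, diff, fids = self._setup()
        sel = ds.select_discriminating_features(model, diff, fids, top_n=12)
        assert "F2" not in sel
        assert set(sel) <= {"F0", "F1"}

    def test_zero_loading_never_selected(self):
        model, diff, fids = self._setup()
        model.p_pred[5] = 0.0
        diff.table.loc["F5", "p_raw"] = 1e-9
        sel = ds.select_discriminating_features(model, diff, fids, top_n=12)
        assert "F5" not in sel
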