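import numpy as np
import pandas as pd
import pytest
import scipy.stats

import icibiome as ib
from icibiome.diffabund import (
    bias_corrected_loglinear,
    cohort_effects,
    hedges_g,
    load_plugin_effects,
    logit_tss_lm,
    prevalence_mask,
    smd_effect,
    wilcoxon_effect,
)


def _labels(table, pattern):
    return pd.Series(pattern, index=table.data.index)


def _table_from(arr, cohort="C"):
    arr = np.asarray(arr, dtype=float)
    df = pd.DataFrame(arr / arr.sum(axis=1, keepdims=True),
                      index=[f"s{i}" for i in range(len(arr))],
                      columns=[f"k__B|s__sp_{j}" for j in range(arr.shape[1])])
    return ib.AbundanceTable(df, cohort=cohort)


class TestWilcoxon:
    def test_extreme_separation_exact_p(self):
        t = _table_from([[1, 9], [2, 8], [3, 7], [4, 6], [5, 5], [6, 4]])
        res = wilcoxon_effect(t, _labels(t, [1, 1, 1, 0, 0, 0]))
        # feature 0: (1,2,3) vs (4,5,6) -> exact two-sided p = 2/20
        assert np.isclose(res.set_index("feature").iloc[0]["p"], 0.1)

    def test_identical_groups_p_one(self):
        t = _table_from([[1, 1]] * 6)
        res = wilcoxon_effect(t, _labels(t, [1, 1, 1, 0, 0, 0]))
        assert (res["p"] == 1.0).all()

    def test_exact_close_to_asymptotic_on_tie_free_data(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.4, 0.9, 10)
        y = rng.uniform(0.2, 0.7, 10)
        exact = scipy.stats.mannwhitneyu(x, y, method="exact").pvalue
        approx = scipy.stats.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert abs(exact - approx) < 0.02
        arr = np.column_stack([np.concatenate([x, y]),
                               1 - np.concatenate([x, y])])
        t = _table_from(arr)
        res = wilcoxon_effect(t, _labels(t, [1] * 10 + [0] * 10))
        assert np.isclose(res.iloc[0]["p"], exact)

    def test_empty_group_rejected(self):
        t = _table_from([[1, 1]] * 4)
        with pytest.raises(ValueError):
            wilcoxon_effect(t, _labels(t, [1, 1, 1, 1]))


class TestSmd:
    def test_hedges_g_formula_oracle(self):
        x = np.array([0.2, 0.4, 0.6])   # mean 0.4, sd 0.2
        y = np.array([0.1, 0.2, 0.3])   # mean 0.2, sd 0.1
        g, var = hedges_g(x, y)
        assert np.isclose(g, 1.0119288, atol=1e-6)  # d=1.2649, J=0.8
        assert np.isclose(var, 6 / 9 + g**2 / 12)

    def test_close_to_statsmodels_effectsize(self):
        from statsmodels.stats.meta_analysis import effectsize_smd

        rng = np.random.default_rng(0)
        x, y = rng.normal(0.5, 0.2, 20), rng.normal(0.3, 0.25, 25)
        g, var = hedges_g(x, y)
        g_sm, var_sm = effectsize_smd(x.mean(), x.std(ddof=1), len(x),
                                      y.mean(), y.std(ddof=1), len(y))
        assert np.isclose(g, g_sm, atol=1e-8)
        assert np.isclose(var, var_sm, rtol=0.05)

    def test_identical_groups_flagged_zero_variance(self):
        t = _table_from([[1, 1]] * 8)
        res = smd_effect(t, _labels(t, [1] * 4 + [0] * 4))
        assert res["effect"].isna().all()  # constant feature: undefined, flagged

    def test_label_swap_flips_sign(self, small_labeled_table):
        table, labels = small_labeled_table
        a = smd_effect(table, labels)
        b = smd_effect(table, 1 - labels)
        assert np.allclose(a["effect"], -b["effect"], equal_nan=True)


class TestLogitTssLm:
    def test_planted_logit_shift_recovered(self):
        rng = np.random.default_rng(2)
        n, p = 100, 40
        group = np.array([0, 1] * (n // 2))
        logs = rng.normal(0, 1, (n, p))
        logs[:, 0] += 1.5 * group
        t = _table_from(np.exp(logs))
        res = logit_tss_lm(t, _labels(t, group)).set_index("feature")
        row = res.iloc[0]
        assert abs(row["effect"] - 1.5) < 2 * row["se"]

    def test_null_p_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(20):
            t = _table_from(np.exp(rng.normal(0, 1, (30, 10))))
            res = logit_tss_lm(t, _labels(t, [0, 1] * 15))
            ps.extend(res["p"])
        assert 0.35 < np.mean(ps) < 0.65
        assert (np.array(ps) < 0.05).mean() < 0.15

    def test_collinear_covariate_rejected(self):
        t = _table_from(np.exp(np.random.default_rng(1).normal(0, 1, (12, 5))))
        labels = _labels(t, [0, 1] * 6)
        cov = pd.DataFrame({"dup": labels.astype(float)}, index=labels.index)
        with pytest.raises(ValueError, match="rank-deficient|aliased"):
            logit_tss_lm(t, labels, covariates=cov)


class TestBiasCorrectedLoglinear:
    def _counts(self, n=100, p=200, planted=20, effect=1.0, seed=0, depth=9.0):
        rng = np.random.default_rng(seed)
        group = np.array([0, 1] * (n // 2))
        logs = rng.normal(depth, 1.0, (n, p))
        logs[:, :planted] += effect * group[:, None]
        counts = pd.DataFrame(np.rint(np.exp(logs)).astype(int),
                              index=[f"s{i}" for i in range(n)],
                              columns=[f"f{j}" for j in range(p)])
        return counts, pd.Series(group, index=counts.index)

    def test_planted_log_fold_change_recovered(self):
        counts, labels = self._counts(effect=1.0)
        res = bias_corrected_loglinear(counts, labels).set_index("feature")
        planted = [f"f{j}" for j in range(20)]
        assert 0.7 < res.loc[planted, "effect"].median() < 1.3
        assert res["converged"].all()

    def test_null_fdr_controlled(self):
        counts, labels = self._counts(planted=0, effect=0.0, seed=5)
        res = bias_corrected_loglinear(counts, labels)
        q = ib.bh_adjust(res["p"])
        assert (q < 0.2).mean() <= 0.25

    def test_intercept_only_design_rejected(self):
        counts, labels = self._counts(n=10, p=5)
        with pytest.raises(ValueError):
            bias_corrected_loglinear(counts, pd.Series(1, index=counts.index))

    def test_low_depth_samples_dropped(self):
        counts, labels = self._counts(n=20, p=10, depth=6.0)
        counts.iloc[0] = 1  # library of 10 reads, under the 1000-read cutoff
        res = bias_corrected_loglinear(counts, labels, library_cutoff=1000)
        assert res["p"].notna().any()


class TestEnsembleProperties:
    def test_methods_agree_on_direction_of_strong_feature(self):
        # a feature planted at log effect 2.0 and prevalence ~0.9 should be
        # called responder-up by every method in nearly every draw
        agree = 0
        runs = 8
        for seed in range(runs):
            cfg = ib.SimulationConfig(
                n_cohorts=1, samples_per_cohort=[60], n_species=60, n_functions=10,
                planted_up=(0,), effect_size=2.0, planted_prevalence=(0.9, 0.95),
                response_rate_per_cohort=[0.5], seed=100 + seed,
            )
            study = ib.generate_study(cfg)
            table = next(iter(study.tables.values()))
            eff = cohort_effects(table, study.metadata, outcome="orr")
            feat = study.truth["planted_up"][0]
            dirs = eff[eff.feature == feat]["direction"]
            if (dirs == "responder_up").all():
                agree += 1
        assert agree >= runs - 1

    def test_prevalence_gate_excludes_rare_features(self, toy_table):
        t = ib.AbundanceTable(toy_table.data.assign(**{"k__B|s__rare": 0.0}))
        mask = prevalence_mask(t, min_prevalence=0.1)
        assert not mask["k__B|s__rare"]

    def test_plugin_effect_table_loaded_with_prefix(self, tmp_path):
        df = pd.DataFrame({
            "feature": ["f1"], "cohort": ["A"], "method": ["deseq2"],
            "effect": [1.2], "se": [0.3], "p": [0.01],
        })
        path = tmp_path / "plugin.tsv"
        df.to_csv(path, sep="\t", index=False)
        out = load_plugin_effects(path)
        assert out["method"].iloc[0] == "plugin:deseq2"

    def test_plugin_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"feature": ["f"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="lacks columns"):
            load_plugin_effects(path)
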