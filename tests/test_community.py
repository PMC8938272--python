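import itertools

import numpy as np
import pandas as pd
import pytest

import icibiome as ib
from icibiome.community import PermanovaResult, eb_batch_correct, permanova
from icibiome.transforms import ClrTable


class TestDiversity:
    def test_uniform_shannon_is_log_k(self):
        assert np.isclose(ib.shannon(np.full(4, 0.25)), np.log(4))

    def test_single_taxon(self):
        assert ib.shannon(np.array([1.0, 0.0])) == 0.0
        assert ib.richness(np.array([1.0, 0.0])) == 1

    def test_closed_form_mixed(self):
        h = ib.shannon(np.array([0.5, 0.25, 0.25]))
        assert np.isclose(h, 0.5 * np.log(2) + 0.5 * np.log(4))  # 1.0397


class TestAitchisonDistance:
    def _clr(self, arr):
        arr = np.asarray(arr, dtype=float)
        df = pd.DataFrame(arr - arr.mean(axis=1, keepdims=True),
                          index=[f"s{i}" for i in range(len(arr))],
                          columns=[f"f{j}" for j in range(arr.shape[1])])
        return ClrTable(df)

    def test_identical_samples_distance_zero(self):
        d = ib.aitchison_distance(self._clr([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        assert d.iloc[0, 1] == 0.0

    def test_two_sample_hand_computation(self):
        c = self._clr([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        expected = np.sqrt(2**2 + 1**2 + 1**2)  # centered rows (0,0,0),(2,-1,-1)
        assert np.isclose(ib.aitchison_distance(c).iloc[0, 1], expected)

    def test_matches_euclidean_of_clr_vectors(self, toy_table):
        c = ib.clr(toy_table)
        d = ib.aitchison_distance(c)
        manual = np.linalg.norm(c.values[0] - c.values[1])
        assert np.isclose(d.iloc[0, 1], manual)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(0)
        c = self._clr(rng.normal(size=(3, 6)))
        d = ib.aitchison_distance(c).values
        assert d[0, 2] <= d[0, 1] + d[1, 2] + 1e-12


def _two_block_distance():
    d = np.ones((6, 6))
    d[:3, :3] = 0
    d[3:, 3:] = 0
    np.fill_diagonal(d, 0)
    meta = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3})
    return d, meta


class TestPermanova:
    def test_perfect_partition_r2_is_one(self):
        d, meta = _two_block_distance()
        res = permanova(d, meta, ["g"], n_perm=99, seed=0)
        assert np.isclose(res.r2("g"), 1.0)
        total = res.table.set_index("term")
        assert np.isclose(total.loc[["g", "Residual"], "R2"].sum(), 1.0)

    def test_p_matches_exhaustive_enumeration(self):
        # all C(6,3)=20 balanced labelings; 2 reproduce the two-block partition
        d, meta = _two_block_distance()
        exceed = 0
        for combo in itertools.combinations(range(6), 3):
            labels = np.array(["b"] * 6)
            labels[list(combo)] = "a"
            res = permanova(d, pd.DataFrame({"g": labels}), ["g"], n_perm=1, seed=0)
            if res.r2("g") >= 1.0 - 1e-9:
                exceed += 1
        assert exceed == 2  # exhaustive p = 2/20 = 0.1
        sampled = permanova(d, meta, ["g"], n_perm=1999, seed=3).p("g")
        assert abs(sampled - 0.1) < 0.03  # binomial error at n_perm=1999

    def test_null_p_approximately_uniform(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(16, 6))
        import scipy.spatial.distance as ssd

        d = ssd.squareform(ssd.pdist(x))
        meta = pd.DataFrame({"g": ["a"] * 8 + ["b"] * 8})
        ps = [permanova(d, meta, ["g"], n_perm=99, seed=s).p("g") for s in range(200)]
        # labels are fixed but the distances carry no group structure; the
        # permutation p across re-drawn data is the real check below
        ps2 = []
        for s in range(60):
            xs = np.random.default_rng(1000 + s).normal(size=(16, 6))
            ds = ssd.squareform(ssd.pdist(xs))
            ps2.append(permanova(ds, meta, ["g"], n_perm=99, seed=s).p("g"))
        assert 0.35 < np.mean(ps2) < 0.65
        assert min(ps) >= 1.0 / 100

    def test_matches_single_factor_reference_implementation(self):
        import scipy.spatial.distance as ssd
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 8))
        x[:10] += 0.8
        d = ssd.squareform(ssd.pdist(x))
        meta = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10})
        ours = permanova(d, meta, ["g"], n_perm=999, seed=1)
        ref = skbio_permanova(DistanceMatrix(d), list(meta["g"]), permutations=999)
        assert np.isclose(ours.table.iloc[0]["F"], ref["test statistic"], rtol=1e-9)
        assert abs(ours.p("g") - ref["p-value"]) < 0.05

    def test_r2_invariant_to_label_renaming(self):
        d, meta = _two_block_distance()
        renamed = meta.replace({"a": "x", "b": "y"})
        r1 = permanova(d, meta, ["g"], n_perm=49, seed=0).r2("g")
        r2 = permanova(d, renamed, ["g"], n_perm=49, seed=0).r2("g")
        assert np.isclose(r1, r2)

    def test_sequential_terms_partition_sums_to_one(self, reference_study):
        study = reference_study
        pooled = ib.merge_cohorts(list(study.tables.values())).renormalized()
        sub = ib.AbundanceTable(pooled.data.iloc[:90], cohort="sub")
        dist = ib.aitchison_distance(ib.clr(sub))
        meta = study.metadata.data.loc[sub.sample_ids]
        res = permanova(dist, meta, ["cohort", "orr", "gender"], n_perm=49, seed=2)
        assert np.isclose(res.table["R2"].iloc[:-1].sum(), 1.0)
        assert isinstance(res, PermanovaResult)

    def test_constant_term_rejected(self):
        d, meta = _two_block_distance()
        meta["c"] = "same"
        with pytest.raises(ValueError, match="'c'"):
            permanova(d, meta, ["c"], n_perm=9, seed=0)


class TestBatchCorrection:
    def _make(self, n_per=30, p=60, shift=2.0, group_effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n = 2 * n_per
        x = rng.normal(0.0, 1.0, (n, p))
        batch = np.array(["b1"] * n_per + ["b2"] * n_per)
        delta = rng.normal(0.0, shift, p) if shift else np.zeros(p)
        delta -= delta.mean()
        x[batch == "b2"] += delta
        group = np.tile([0, 1], n // 2)  # orthogonal to batch
        x[:, :5] += group_effect * group[:, None]
        x[:, 5:10] -= group_effect * group[:, None]
        x -= x.mean(axis=1, keepdims=True)
        df = pd.DataFrame(x, index=[f"s{i}" for i in range(n)],
                          columns=[f"f{j}" for j in range(p)])
        return ClrTable(df), pd.Series(batch, index=df.index), group, delta

    def test_single_batch_returns_input(self):
        clr_t, batch, _, _ = self._make(shift=0.0)
        single = pd.Series("only", index=batch.index)
        out = eb_batch_correct(clr_t, single)
        assert np.abs(out.values - clr_t.values).max() < 1e-6

    def test_location_shift_removed(self):
        clr_t, batch, _, _ = self._make(shift=2.0)
        pre_gap = (clr_t.data[batch == "b2"].mean() - clr_t.data[batch == "b1"].mean())
        out = eb_batch_correct(clr_t, batch)
        post_gap = (out[batch == "b2"].mean() - out[batch == "b1"].mean())
        assert post_gap.abs().mean() < 0.05 * pre_gap.abs().mean()

    def test_orthogonal_group_effect_preserved(self):
        clr_t, batch, group, _ = self._make(shift=2.0, group_effect=1.0, seed=3)
        out = eb_batch_correct(clr_t, batch)
        diff = out[group == 1].mean() - out[group == 0].mean()
        contrast = (diff.iloc[:5].mean() - diff.iloc[5:10].mean()) / 2.0
        assert abs(contrast - 1.0) < 0.2

    def test_singleton_batch_rejected(self):
        clr_t, batch, _, _ = self._make(n_per=2)
        bad = batch.copy()
        bad.iloc[0] = "lonely"
        with pytest.raises(ValueError, match="singleton"):
            eb_batch_correct(clr_t, bad)


class TestFisherExact:
    @pytest.mark.parametrize("table,expected,tol", [
        ((17, 38, 30, 25), 0.0203, 5e-4),   # BRAF-mutant cohort comparison
        ((2, 0, 0, 2), 1 / 3, 1e-9),        # enumeration over C(4,2)=6 tables
    ])
    def test_reference_values(self, table, expected, tol):
        assert abs(ib.fisher_exact_test(*table) - expected) < tol

    def test_previous_therapy_comparison(self):
        # matches R fisher.test to 1e-7 (printed as 0.03 at one significant digit)
        p = ib.fisher_exact_test(11, 44, 22, 33)
        assert abs(p - 0.03661911) < 1e-7

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ib.fisher_exact_test(-1, 2, 3, 4)
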