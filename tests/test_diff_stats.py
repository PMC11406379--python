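import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from taxafunc import diff_stats as ds
from taxafunc.types import GeneCountTable, GeneSet, GeneSetCollection, ValidationError


def two_group(n1=2, n2=2):
    samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    groups = {s: ("A" if s.startswith("a") else "B") for s in samples}
    return samples, groups


class TestFilterFeatures:
    def test_all_zero_feature_dropped(self):
        samples, groups = two_group()
        counts = pd.DataFrame([[0, 0, 0, 0], [5, 6, 0, 0]], columns=samples,
                              index=["f0", "f1"])
        kept = ds.filter_features(counts, groups)
        assert list(kept) == ["f1"]

    def test_min_count_zero_retains_all(self):
        samples, groups = two_group()
        counts = pd.DataFrame([[0, 0, 0, 0]], columns=samples, index=["f0"])
        assert list(ds.filter_features(counts, groups, min_count=0)) == ["f0"]

    def test_everything_filtered_is_an_error(self):
        samples, groups = two_group()
        counts = pd.DataFrame([[0, 0, 0, 0]], columns=samples, index=["f0"])
        with pytest.raises(ValidationError, match="filter"):
            ds.filter_features(counts, groups)


class TestTmmFactors:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, size=200)
        counts = pd.DataFrame({"s1": col, "s2": col, "s3": col})
        assert np.allclose(ds.tmm_factors(counts), 1.0)

    def test_pure_depth_scaling_cancels(self):
        rng = np.random.default_rng(1)
        col = rng.integers(10, 1000, size=300)
        counts = pd.DataFrame({"s1": col, "s2": 2 * col, "s3": 5 * col})
        assert np.allclose(ds.tmm_factors(counts), 1.0, atol=1e-6)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.05, size=(400, 4)),
            columns=list("abcd"),
        )
        factors = ds.tmm_factors(counts)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-12)

    def test_zero_library_is_an_error(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(ValidationError):
            ds.tmm_factors(counts)


def binomial_oracle(s1, s2, n1, n2):
    """Exhaustive enumeration of the phi=0 conditional null: all splits of
    the total whose probability does not exceed the observed one."""
    t = s1 + s2
    if t == 0:
        return 1.0
    probs = binom.pmf(np.arange(t + 1), t, n1 / (n1 + n2))
    return min(1.0, probs[probs <= probs[s1] * (1 + 1e-7)].sum())


class TestExactTest:
    def test_symmetric_counts_give_p1_and_zero_fc(self):
        samples, groups = two_group()
        counts = pd.DataFrame([[7, 9, 7, 9], [3, 5, 3, 5]], columns=samples,
                              index=["f0", "f1"])
        res = ds.nb_exact_test(counts, groups, dispersion=0.0)
        assert np.allclose(res.table["pvalue"], 1.0)
        assert np.allclose(res.table["log2FC"], 0.0)

    def test_phi_zero_equals_binomial_on_3_vs_0(self):
        # single sample per group, equal libraries: p0 = 1/2
        p = ds.exact_nb_pvalue(3, 0, 1, 1, 0.0)
        assert p == pytest.approx(binomial_oracle(3, 0, 1, 1), abs=1e-10)
        assert p == pytest.approx(2 * 0.5**3, abs=1e-10)

    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3)])
    def test_phi_zero_matches_enumeration_on_small_totals(self, n1, n2):
        for t in range(0, 21):
            for s1 in range(t + 1):
                assert ds.exact_nb_pvalue(s1, t - s1, n1, n2, 0.0) == pytest.approx(
                    binomial_oracle(s1, t - s1, n1, n2), abs=1e-10
                )

    def test_doubling_counts_increases_evidence(self):
        p1 = ds.exact_nb_pvalue(6, 2, 1, 1, 0.0)
        p2 = ds.exact_nb_pvalue(12, 4, 1, 1, 0.0)
        assert p2 < p1

    def test_more_than_two_groups_redirects_to_pairwise(self):
        counts = pd.DataFrame([[5, 6, 7]], columns=["a", "b", "c"], index=["f"])
        with pytest.raises(ValidationError, match="pairwise"):
            ds.nb_exact_test(counts, {"a": "A", "b": "B", "c": "C"})

    def test_dispersion_recovered_from_nb_data(self):
        rng = np.random.default_rng(9)
        phi, mu = 0.15, 200.0
        lam = rng.gamma(1 / phi, mu * phi, size=(500, 8))
        counts = pd.DataFrame(rng.poisson(lam), columns=[f"s{i}" for i in range(8)])
        groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        res = ds.nb_exact_test(counts, groups)
        assert res.dispersion == pytest.approx(phi, rel=0.25)

    def test_pairwise_and_group_significance(self):
        rng = np.random.default_rng(4)
        samples = [f"{g}{i}" for g in "abc" for i in range(3)]
        groups = {s: s[0] for s in samples}
        counts = pd.DataFrame(
            rng.poisson(100, size=(20, 9)), columns=samples,
            index=[f"f{i}" for i in range(20)],
        )
        # f0 strongly up in group a versus both others
        counts.loc["f0", [s for s in samples if s[0] == "a"]] = 1000
        results = ds.pairwise_exact_tests(counts, groups, dispersion=0.0)
        assert set(results) == {("a", "b"), ("a", "c"), ("b", "c")}
        assert "f0" in ds.significant_in_group(results, "a")


class TestBhAdjust:
    def test_hand_computed_example(self):
        out = ds.bh_adjust([0.01, 0.04, 0.03])
        assert np.allclose(out, [0.03, 0.04, 0.04])

    def test_degenerate_cases(self):
        assert np.allclose(ds.bh_adjust([0.2, 0.2, 0.2]), 0.2)
        assert ds.bh_adjust([0.123]) == pytest.approx([0.123])

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        assert np.allclose(ds.bh_adjust(p)[perm], ds.bh_adjust(p[perm]))

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        adj = ds.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ds.bh_adjust([0.5, 1.5])


class TestTpm:
    def make(self, counts, lengths):
        df = pd.DataFrame(counts)
        return GeneCountTable(counts=df, lengths=pd.Series(lengths, index=df.index))

    def test_single_gene_is_a_million(self):
        t = self.make({"s": [10]}, [500])
        assert ds.tpm(t)["s"].tolist() == [1e6]

    def test_length_normalization_hand_values(self):
        t = self.make({"s": [10, 10]}, [1000, 2000])
        out = ds.tpm(t)["s"]
        assert out.iloc[0] == pytest.approx(666666.67, abs=0.01)
        assert out.iloc[1] == pytest.approx(333333.33, abs=0.01)

    def test_columns_sum_to_a_million(self):
        rng = np.random.default_rng(7)
        t = self.make(
            {f"s{i}": rng.integers(0, 500, 50) + 1 for i in range(3)},
            rng.integers(200, 5000, 50),
        )
        assert np.allclose(ds.tpm(t).sum(axis=0), 1e6, atol=1e-3)

    def test_zero_count_gene_is_zero(self):
        t = self.make({"s": [0, 5]}, [1000, 1000])
        assert ds.tpm(t)["s"].iloc[0] == 0.0


def brute_force_es(scores, hit_genes, genes, p=1.0):
    """Independent running-sum enumeration used as the GSEA oracle."""
    order = np.argsort(-np.asarray(scores), kind="mergesort")
    nr = sum(abs(scores[i]) ** p for i in order if genes[i] in hit_genes)
    n_miss = len(genes) - len(hit_genes)
    run, best = 0.0, 0.0
    for i in order:
        if genes[i] in hit_genes:
            run += abs(scores[i]) ** p / nr
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


class TestGseaPreranked:
    def ranked(self):
        return pd.Series([4.0, 3.0, 2.0, 1.0], index=["g1", "g2", "g3", "g4"])

    def sets(self):
        coll = GeneSetCollection()
        coll["TOP2"] = GeneSet("top", ["g1", "g2"])
        coll["BOT2"] = GeneSet("bottom", ["g3", "g4"])
        return coll

    def test_es_matches_brute_force_oracle(self):
        ranked = self.ranked()
        out = ds.gsea_preranked(ranked, self.sets(), n_perm=50, seed=0)
        expected = brute_force_es(
            ranked.tolist(), {"g1", "g2"}, list(ranked.index)
        )
        assert out.loc["TOP2", "es"] == pytest.approx(expected, abs=1e-9)

    def test_mirror_set_negates_es(self):
        out = ds.gsea_preranked(self.ranked(), self.sets(), n_perm=50, seed=0)
        assert out.loc["BOT2", "es"] == pytest.approx(-out.loc["TOP2", "es"], abs=1e-9)

    def test_oracle_agreement_on_random_sets(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(30)]
        scores = np.sort(rng.normal(size=30))[::-1]
        ranked = pd.Series(scores, index=genes)
        coll = GeneSetCollection()
        for k in range(5):
            members = rng.choice(genes, size=8, replace=False).tolist()
            coll[f"S{k}"] = GeneSet("rand", members)
        out = ds.gsea_preranked(ranked, coll, n_perm=20, seed=1)
        for k in range(5):
            expected = brute_force_es(scores, set(coll[f"S{k}"].genes), genes)
            assert out.loc[f"S{k}", "es"] == pytest.approx(expected, abs=1e-9)

    def test_identical_seed_reproduces_results(self):
        a = ds.gsea_preranked(self.ranked(), self.sets(), n_perm=200, seed=42)
        b = ds.gsea_preranked(self.ranked(), self.sets(), n_perm=200, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_sets_skipped_with_reason(self):
        coll = GeneSetCollection()
        coll["ALL"] = GeneSet("covers list", ["g1", "g2", "g3", "g4"])
        coll["NONE"] = GeneSet("disjoint", ["x1", "x2"])
        out = ds.gsea_preranked(self.ranked(), coll, n_perm=10, seed=0)
        assert out.empty
        assert {name for name, _ in out.attrs["skipped"]} == {"ALL", "NONE"}

    def test_duplicate_genes_rejected(self):
        ranked = pd.Series([1.0, 2.0], index=["g1", "g1"])
        with pytest.raises(ValidationError):
            ds.gsea_preranked(ranked, self.sets(), n_perm=10, seed=0)
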