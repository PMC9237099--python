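"""Downstream analyses: CorrIndex, networks, Gini, statistics, GSEA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from commtensor import (
    LRCatalog,
    LRPair,
    build_lr_sets,
    cluster_samples,
    compare_groups,
    corrindex,
    factor_network,
    gini,
    ordinal_correlation,
    prerank_gsea,
)
from commtensor.downstream import LRSetCollection, _enrichment_scores


class TestCorrindex:
    def test_self_distance_zero(self, results_factory):
        res = results_factory(np.random.default_rng(0))
        assert corrindex(res, res) == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self, results_factory):
        res = results_factory(np.random.default_rng(1))
        perm = [2, 0, 1]
        permuted = results_factory(np.random.default_rng(1))
        for d in res.factors:
            permuted.factors[d] = res.factors[d].iloc[:, perm]
            permuted.factors[d].columns = res.factors[d].columns
        assert corrindex(res, permuted) == pytest.approx(0.0, abs=1e-12)

    def test_positive_scaling_invariance(self, results_factory):
        res = results_factory(np.random.default_rng(2))
        scaled = results_factory(np.random.default_rng(2))
        for d in res.factors:
            scaled.factors[d] = res.factors[d] * [0.3, 5.0, 42.0]
        assert corrindex(res, scaled) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_bounds(self, results_factory):
        a = results_factory(np.random.default_rng(3))
        b = results_factory(np.random.default_rng(4))
        d1, d2 = corrindex(a, b), corrindex(b, a)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert 0.0 <= d1 <= 1.0

    def test_per_dimension_mode(self, results_factory):
        a = results_factory(np.random.default_rng(5))
        b = results_factory(np.random.default_rng(6))
        out = corrindex(a, b, mode="per_dimension")
        assert set(out) == {"contexts", "pairs", "senders", "receivers", "stacked"}
        assert out["stacked"] == pytest.approx(corrindex(a, b))
        assert all(0.0 <= v <= 1.0 for v in out.values())

    def test_rank_mismatch_rejected(self, results_factory):
        a = results_factory(np.random.default_rng(0), rank=3)
        b = results_factory(np.random.default_rng(0), rank=2)
        with pytest.raises(ValueError, match="rank"):
            corrindex(a, b)

    def test_label_mismatch_rejected(self, results_factory):
        a = results_factory(np.random.default_rng(0))
        b = results_factory(np.random.default_rng(0))
        b.factors["senders"].index = ["x", "y", "z"]
        with pytest.raises(ValueError, match="labels"):
            corrindex(a, b)


class TestGini:
    def test_equal_weights_zero(self):
        assert gini([5, 5, 5, 5]) == pytest.approx(0.0)

    def test_two_point_case(self):
        assert gini([1, 0]) == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [4, 10, 100])
    def test_single_nonzero(self, n):
        w = np.zeros(n)
        w[0] = 3.0
        assert gini(w) == pytest.approx((n - 1) / n)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0.001, 1e3), min_size=2, max_size=30),
        st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, w, c):
        assert gini(np.array(w) * c) == pytest.approx(gini(w), rel=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            gini([0.0, 0.0])


class TestFactorNetwork:
    def test_outer_product_example(self, results_factory):
        res = results_factory(np.random.default_rng(0), shape=(2, 2, 2, 2), rank=1)
        res.factors["senders"].iloc[:, 0] = [1.0, 0.0]
        res.factors["receivers"].iloc[:, 0] = [0.0, 1.0]
        net = factor_network(res, 1)
        np.testing.assert_array_equal(net.adjacency.to_numpy(), [[0, 1], [0, 0]])
        assert net.gini == pytest.approx(0.75)  # one live edge of four

    def test_uniform_loadings_give_zero_gini(self, results_factory):
        res = results_factory(np.random.default_rng(0), rank=1)
        res.factors["senders"].iloc[:, 0] = 0.4
        res.factors["receivers"].iloc[:, 0] = 0.7
        assert factor_network(res, 1).gini == pytest.approx(0.0)

    def test_adjacency_rank_one(self, sim_fit):
        res, _ = sim_fit
        for f in res.factor_names:
            sv = np.linalg.svd(
                factor_network(res, f).adjacency.to_numpy(), compute_uv=False
            )
            assert sv[1:].max() <= 1e-10 * max(sv[0], 1e-30)


class TestOrdinalCorrelation:
    def test_monotone_increasing(self):
        out = ordinal_correlation([1.0, 2.0, 3.0], ["a", "b", "c"])
        assert out.rho == pytest.approx(1.0)
        assert out.defined

    def test_monotone_decreasing(self):
        out = ordinal_correlation([3.0, 2.0, 1.0], ["a", "b", "c"])
        assert out.rho == pytest.approx(-1.0)

    def test_tied_ranks(self):
        out = ordinal_correlation([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])
        assert out.rho == pytest.approx(1.0)

    def test_constant_loadings_flagged(self):
        out = ordinal_correlation([1.0, 1.0, 1.0], ["a", "b", "c"])
        assert not out.defined
        assert np.isnan(out.rho)


class TestCompareGroups:
    def _loadings(self, values):
        return pd.DataFrame({"factor_1": values})

    def test_identical_groups_t_zero(self):
        df = compare_groups(
            self._loadings([1.0, 2.0, 1.0, 2.0]), ["g1", "g1", "g2", "g2"]
        )
        assert df["t"].iloc[0] == pytest.approx(0.0)

    def test_single_comparison_unadjusted(self):
        df = compare_groups(
            self._loadings([1.0, 2.0, 5.0, 6.0]), ["a", "a", "b", "b"]
        )
        assert len(df) == 1
        assert df["pvalue_bonferroni"].iloc[0] == pytest.approx(df["pvalue"].iloc[0])

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 0.01, 3), rng.normal(1, 0.01, 3)])
        df = compare_groups(self._loadings(vals), ["a"] * 3 + ["b"] * 3)
        assert df["pvalue_bonferroni"].iloc[0] < 0.05

    def test_bonferroni_is_count_times_raw_capped(self):
        rng = np.random.default_rng(1)
        loadings = pd.DataFrame(
            rng.random((9, 2)), columns=["factor_1", "factor_2"]
        )
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        df = compare_groups(loadings, groups)
        assert len(df) == 6  # 2 factors x 3 group pairs
        np.testing.assert_allclose(
            df["pvalue_bonferroni"], np.minimum(df["pvalue"] * 6, 1.0)
        )

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(self._loadings([1.0, 2.0, 3.0]), ["a", "a", "b"])


class TestClusterSamples:
    def test_two_clouds_split(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.1, (5, 3)), rng.normal(10, 0.1, (5, 3))])
        loadings = pd.DataFrame(x, columns=["factor_1", "factor_2", "factor_3"])
        labels, _ = cluster_samples(loadings, n_clusters=2)
        assert labels.iloc[:5].nunique() == 1
        assert labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[9]

    def test_duplicate_rows_cocluster(self):
        loadings = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [8.0, 9.0], [8.0, 9.0]],
            columns=["factor_1", "factor_2"],
        )
        labels, _ = cluster_samples(loadings, n_clusters=2)
        assert labels.iloc[0] == labels.iloc[1]
        assert labels.iloc[2] == labels.iloc[3]

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        loadings = pd.DataFrame(
            {"factor_1": rng.random(6), "factor_2": np.ones(6)}
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            labels, _ = cluster_samples(loadings, n_clusters=2)
        assert labels.nunique() == 2


def _toy_catalog():
    return LRCatalog(
        [
            LRPair("g1&g2^g3", ("g1", "g2"), ("g3",)),
            LRPair("g1^g3", ("g1",), ("g3",)),
            LRPair("g4^g5", ("g4",), ("g5",)),
        ]
    )


class TestBuildLrSets:
    def test_requires_all_genes(self):
        sets = build_lr_sets(
            {"pw": {"g1", "g2", "g3"}}, _toy_catalog(), min_size=1
        )
        assert sets.sets["pw"] == {"g1&g2^g3", "g1^g3"}

    def test_missing_subunit_excludes_pair(self):
        sets = build_lr_sets({"pw": {"g1", "g3"}}, _toy_catalog(), min_size=1)
        assert sets.sets["pw"] == {"g1^g3"}

    def test_min_size_filter(self):
        sets = build_lr_sets(
            {"small": {"g4", "g5"}, "big": {"g1", "g2", "g3"}},
            _toy_catalog(),
            min_size=2,
        )
        assert "small" not in sets.sets  # 1 pair < min_size 2
        assert "big" in sets.sets


def _classic_ks_es(ranked_ids, members):
    """Unweighted running-sum KS oracle (equal hit steps)."""
    n, m = len(ranked_ids), len(members)
    best = 0.0
    run = 0.0
    for pid in ranked_ids:
        run += 1.0 / m if pid in members else -1.0 / (n - m)
        if abs(run) > abs(best):
            best = run
    return best


class TestPrerankGsea:
    def _ranking(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.sort(rng.random(n))[::-1]
        return pd.Series(vals, index=[f"p{i:02d}" for i in range(n)]).to_frame(
            "factor_1"
        )

    def test_top_set_es_near_one(self):
        ranking = self._ranking()
        # all loading mass on the top block
        ranking.iloc[5:, 0] = 0.0
        sets = LRSetCollection({"top": set(ranking.index[:5])}, min_size=5)
        out = prerank_gsea(ranking, sets, n_perm=99, seed=0)
        assert out["es"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_weight_zero_matches_classic_ks(self):
        ranking = self._ranking(seed=3)
        members = set(ranking.index[::3][:8])
        sets = LRSetCollection({"s": members}, min_size=5)
        out = prerank_gsea(ranking, sets, n_perm=9, weight=0.0, seed=0)
        oracle = _classic_ks_es(list(ranking.index), members)
        assert out["es"].iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_weighted_es_matches_bruteforce(self):
        ranking = self._ranking(seed=4)
        members = set(list(ranking.index[2:6]) + [ranking.index[20]])
        sets = LRSetCollection({"s": members}, min_size=5)
        out = prerank_gsea(ranking, sets, n_perm=9, weight=1.0, seed=0)
        # direct loop with |loading| hit increments
        w = ranking["factor_1"]
        denom = sum(abs(w[p]) for p in members)
        run, best = 0.0, 0.0
        for pid in ranking.index:
            if pid in members:
                run += abs(w[pid]) / denom
            else:
                run -= 1.0 / (len(ranking) - len(members))
            if abs(run) > abs(best):
                best = run
        assert out["es"].iloc[0] == pytest.approx(best, abs=1e-12)

    def test_complement_set_has_opposite_sign(self):
        # 6-pair toy ranking with equal weights
        ranking = pd.Series(
            [1.0] * 6, index=[f"p{i}" for i in range(6)]
        ).to_frame("factor_1")
        top = {"p0", "p1", "p2"}
        rest = {"p3", "p4", "p5"}
        sets = LRSetCollection({"top": top, "rest": rest}, min_size=3)
        out = prerank_gsea(ranking, sets, n_perm=9, seed=0).set_index("set")
        assert out.loc["top", "es"] > 0
        assert out.loc["rest", "es"] <= 0

    def test_bh_adjustment_across_factors(self):
        rng = np.random.default_rng(5)
        rankings = pd.DataFrame(
            rng.random((40, 2)),
            index=[f"p{i:02d}" for i in range(40)],
            columns=["factor_1", "factor_2"],
        )
        sets = LRSetCollection(
            {f"s{k}": set(rng.choice(rankings.index, 10, replace=False))
             for k in range(3)},
            min_size=5,
        )
        out = prerank_gsea(rankings, sets, n_perm=49, seed=1)
        assert len(out) == 6
        assert (out["pvalue_bh"] >= out["pvalue"] - 1e-12).all()
        assert (out["pvalue_bh"] <= 1.0).all()

    def test_set_outside_universe_rejected(self):
        ranking = self._ranking()
        sets = LRSetCollection({"bad": {"zzz"} | set(ranking.index[:9])}, min_size=5)
        with pytest.raises(ValueError, match="outside"):
            prerank_gsea(ranking, sets, n_perm=9)

    def test_determinism(self):
        ranking = self._ranking(seed=6)
        sets = LRSetCollection({"s": set(ranking.index[:10])}, min_size=5)
        a = prerank_gsea(ranking, sets, n_perm=99, seed=42)
        b = prerank_gsea(ranking, sets, n_perm=99, seed=42)
        pd.testing.assert_frame_equal(a, b)
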