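import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gsabench.benchmark import (
    categorize,
    collect_records,
    method_metrics,
    overall_relevance_test,
    rank_methods,
    robust_z,
    scenario_rankings,
    target_rank_pct,
)
from gsabench.reference import published_method_summary, published_scenario_ranks


def _table(ps, target="T"):
    ids = [target] + [f"s{i}" for i in range(len(ps) - 1)]
    return pd.DataFrame({"set_id": ids, "p_value": ps,
                         "size_used": 10, "statistic": 0.0})


class TestTargetRank:
    def test_thirteenth_of_259(self):
        ps = np.concatenate([[0.001 * 13], np.linspace(0.001, 0.012, 12),
                             np.linspace(0.2, 0.9, 246)])
        assert target_rank_pct(_table(ps), "T") == pytest.approx(100 * 13 / 259)

    def test_unique_minimum(self):
        assert target_rank_pct(_table([0.001, 0.5, 0.6, 0.7]), "T") == pytest.approx(25.0)

    def test_all_tied_gets_average_rank(self):
        n = 8
        expect = 100 * (n + 1) / (2 * n)
        assert target_rank_pct(_table([0.5] * n), "T") == pytest.approx(expect)

    def test_absent_target_is_error(self):
        with pytest.raises(KeyError):
            target_rank_pct(_table([0.1, 0.2]), "missing")


class TestMetrics:
    def _records(self):
        return pd.DataFrame({
            "dataset": ["d1", "d2", "d3"] * 2,
            "method_id": ["A"] * 3 + ["B"] * 3,
            "target_p": [0.1, 0.2, 0.3, 0.01, 0.04, 0.2],
            "target_rank_pct": [10, 20, 30, 5, 15, 50],
        })

    def test_medians_and_sensitivity(self):
        m = method_metrics(self._records())
        assert m.loc["A", "med_p"] == pytest.approx(0.2)
        assert m.loc["B", "sens_at_0.05"] == pytest.approx(2 / 3)
        assert m.loc["B", "med_rank"] == pytest.approx(15)

    def test_collect_records_pulls_target_values(self):
        res = {"d1": {"A": _table([0.02, 0.5, 0.9])}}
        rec = collect_records(res, {"d1": "T"})
        assert rec.loc[0, "target_p"] == 0.02
        assert rec.loc[0, "target_rank_pct"] == pytest.approx(100 / 3)


class TestRelevanceTest:
    def _rec(self, ps):
        return pd.DataFrame({
            "dataset": [f"d{i}" for i in range(len(ps))],
            "method_id": "A", "target_p": ps,
            "target_rank_pct": np.asarray(ps) * 100})

    def test_uniformly_small_p_is_overwhelming(self):
        out = overall_relevance_test(self._rec([0.01] * 42))
        assert out.loc["A", "wilcoxon_p_vs_half"] < 1e-6

    def test_symmetric_around_half_is_null(self):
        ps = [0.3, 0.7, 0.4, 0.6, 0.45, 0.55, 0.35, 0.65]
        out = overall_relevance_test(self._rec(ps))
        assert 0.3 < out.loc["A", "wilcoxon_p_vs_half"] < 0.7

    def test_matches_signed_rank_enumeration_n8(self, rng):
        ps = rng.uniform(0.05, 0.95, size=8)
        out = overall_relevance_test(self._rec(ps))
        d = ps - 0.5
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        # exact null: all 2^8 sign assignments equally likely
        ws = [np.sum(ranks[list(signs)])
              for signs in (np.array(c, bool) for c in itertools.product([0, 1], repeat=8))]
        expect = np.mean([w <= w_obs for w in ws])
        assert out.loc["A", "wilcoxon_p_vs_half"] == pytest.approx(expect)


class TestRobustZ:
    def test_reproduces_published_sensitivity_z(self):
        ms = published_method_summary()
        cat1 = ms[ms["category"] == "I"]
        z = robust_z(cat1["med_p"])
        byid = dict(zip(cat1.index, z))
        assert round(byid["PLAGE"], 1) == -1.5
        assert round(byid["CAMERA"], 1) == 3.4

    def test_zero_mad_is_error(self):
        with pytest.raises(ValueError, match="MAD"):
            robust_z([1.0, 1.0, 1.0, 5.0])

    def test_symmetric_values_have_zero_median_z(self):
        z = robust_z([1, 2, 3, 4, 5])
        assert np.median(z) == 0.0


class TestCategorize:
    @pytest.mark.parametrize("fp,expected", [(2.5, "I"), (4.9, "II"), (2.0, "I")])
    def test_published_boundaries(self, fp, expected):
        assert categorize(fp) == expected

    def test_published_fp_column_reproduces_12_4_split(self):
        ms = published_method_summary()
        derived = {m: categorize(ms.loc[m, "fp_pct_0.01"]) for m in ms.index}
        assert derived == dict(ms["category"])
        assert sum(v == "I" for v in derived.values()) == 12


class TestRankMethods:
    def test_reproduces_published_table(self):
        ms = published_method_summary()
        zt = rank_methods(ms[["med_p", "med_rank", "fp_pct_0.01"]],
                          categories=dict(ms["category"]))
        assert zt.loc["PLAGE", "z_sum"] == pytest.approx(-1.86, abs=0.01)
        assert zt.loc["MRGSE", "z_sum"] == pytest.approx(-3.54, abs=0.011)
        assert zt.loc["PLAGE", "rank_in_category"] == 1
        assert zt.loc["PADOG", "rank_in_category"] == 3
        assert zt.loc["MRGSE", "rank_in_category"] == 1

    def test_tied_methods_get_adjacent_ranks_by_id(self):
        metrics = pd.DataFrame({
            "med_p": [0.1, 0.1, 0.3, 0.4],
            "med_rank": [20.0, 20.0, 40.0, 50.0],
        }, index=["MB", "MA", "MC", "MD"])
        zt = rank_methods(metrics, categories={m: "I" for m in metrics.index})
        assert zt.loc["MA", "rank_in_category"] == 1   # id breaks the tie
        assert zt.loc["MB", "rank_in_category"] == 2

    def test_small_category_is_error(self):
        metrics = pd.DataFrame({"med_p": [0.1, 0.2], "med_rank": [10.0, 20.0]},
                               index=["A", "B"])
        with pytest.raises(ValueError, match="fewer than 3"):
            rank_methods(metrics, categories={"A": "I", "B": "I"})


class TestScenarios:
    def test_published_overall_vs_unpaired_spearman(self):
        sr = published_scenario_ranks()
        cat1 = sr[sr["category"] == "I"]
        rho = stats.spearmanr(cat1["overall"], cat1["unpaired"]).statistic
        assert round(rho, 2) == 0.98

    def test_identical_and_reversed_rankings(self):
        r = np.arange(1, 13)
        assert stats.spearmanr(r, r).statistic == pytest.approx(1.0)
        assert stats.spearmanr(r, r[::-1]).statistic == pytest.approx(-1.0)

    def test_scenario_rankings_partition_and_agree(self, rng):
        methods = ["M1", "M2", "M3", "M4"]
        datasets = [f"d{i}" for i in range(8)]
        rows = []
        for j, m in enumerate(methods):
            for i, d in enumerate(datasets):
                rows.append({"dataset": d, "method_id": m,
                             "target_p": 0.05 * (j + 1) + 0.01 * rng.uniform(),
                             "target_rank_pct": 10.0 * (j + 1) + rng.uniform()})
        records = pd.DataFrame(rows)
        feats = pd.DataFrame({
            "n_samples": [10, 10, 10, 10, 30, 30, 30, 30],
            "target_set_size": [20, 80, 20, 80, 20, 80, 20, 80],
            "paired": [True, False] * 4,
            "pct_de_genes": np.linspace(5, 40, 8),
        }, index=datasets)
        reports = scenario_rankings(records, feats,
                                    categories={m: "I" for m in methods})
        assert {r.factor for r in reports} == {
            "sample_size", "set_size", "design", "effect"}
        for rep in reports:
            names = set(rep.subset_tables)
            covered = set()
            for g in names:
                covered |= set(records["dataset"][
                    records["dataset"].isin(
                        feats.index[_mask(feats, rep.factor, rep.cutoff, g)])])
            assert covered == set(datasets)
            # a consistently ordered fixture keeps every subset ranking aligned
            for g, by_cat in rep.spearman_vs_overall.items():
                assert by_cat["I"] == pytest.approx(1.0)


def _mask(feats, factor, cutoff, group):
    col = {"sample_size": "n_samples", "set_size": "target_set_size",
           "design": "paired", "effect": "pct_de_genes"}[factor]
    if factor == "design":
        return feats[col].astype(bool) if group == "paired" else ~feats[col].astype(bool)
    return feats[col] < cutoff if group == "small" else feats[col] >= cutoff
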