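"""Small-instance exactness checks: every statistic with an enumerable
null is compared against brute-force enumeration, and every closed-form
piece against independent arithmetic."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from gsabench.datamodel import ExpressionDataset, GeneSetCollection
from gsabench.genestats import GeneStats, moderated_t
from gsabench.methods import (
    DatasetStats,
    MethodSpec,
    camera_test,
    gage_test,
    globaltest_test,
    gsa_maxmean_test,
    gsea_es,
    gseap_test,
    maxmean,
    mean_rank_test,
    ora_select_de,
    ora_test,
    padog_test,
    padog_weights,
    sigpathway_test,
)
from gsabench.methods.fcs import _subset_quadratic_moments


def _gs(p, t=None, lfc=None, ids=None):
    p = np.asarray(p, dtype=float)
    t = np.asarray(t if t is not None else stats.norm.isf(p / 2), dtype=float)
    lfc = np.asarray(lfc if lfc is not None else t, dtype=float)
    ids = ids or [f"g{i:03d}" for i in range(len(p))]
    return GeneStats(gene_ids=ids, t_mod=t, p=p, lfc=lfc,
                     s2_post=np.ones(len(p)), df_resid=5.0,
                     df_prior=1.0, s2_prior=1.0)


def _ds(expr, paired=False, name="t"):
    expr = np.asarray(expr, dtype=float)
    g, n = expr.shape
    kw = {"block": np.array(list(range(n // 2)) * 2)} if paired else {}
    return ExpressionDataset(
        expr=expr, feature_ids=[f"g{i:03d}" for i in range(g)],
        sample_ids=[f"s{i}" for i in range(n)],
        group=np.array([1] * (n // 2) + [0] * (n // 2)), name=name, **kw)


# ---------------------------------------------------------------------------


class TestOra:
    def test_hypergeometric_matches_enumeration(self):
        # universe 10, DE list of 4, set of 5, overlap 3
        universe = [f"g{i}" for i in range(10)]
        de = universe[:4]
        gene_set = universe[:3] + universe[4:6]   # overlap = 3
        r = ora_test(de, universe, gene_set)
        # enumerate every possible DE list of size 4; overlap with the set
        count = sum(
            1 for combo in itertools.combinations(range(10), 4)
            if len(set(combo) & {0, 1, 2, 4, 5}) >= 3
        )
        assert r.p_value == pytest.approx(count / math.comb(10, 4))
        assert r.p_value == pytest.approx(66 / 252)
        assert r.statistic == 3

    def test_empty_de_list_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        r = ora_test([], universe, universe[:5])
        assert r.p_value == 1.0

    def test_set_equal_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(6)]
        r = ora_test(universe[:2], universe, universe)
        assert r.p_value == 1.0

    def test_de_cascade_rule1_fdr(self):
        p = np.concatenate([np.full(300, 1e-6), np.linspace(0.4, 1, 700)])
        de = ora_select_de(_gs(p, lfc=np.zeros(1000)))
        assert len(de) == 300

    def test_de_cascade_rule2_fold_change(self):
        # few FDR hits, but 250 genes with p<0.05 and |lfc|>log2(1.5)
        p = np.concatenate([np.full(250, 0.02), np.linspace(0.5, 1, 750)])
        lfc = np.concatenate([np.full(250, 1.0), np.zeros(750)])
        de = ora_select_de(_gs(p, lfc=lfc))
        assert len(de) == 250

    def test_de_cascade_rule3_top_percent(self):
        p = np.linspace(0.2, 1, 1000)
        de = ora_select_de(_gs(p, lfc=np.zeros(1000)))
        assert len(de) == 10     # ceil(1000/100)
        assert de == [f"g{i:03d}" for i in range(10)]


class TestMrgse:
    def test_exact_p_two_best_of_five(self):
        r = mean_rank_test(_gs([0.01, 0.02, 0.5, 0.6, 0.7]), ["g000", "g001"])
        assert r.p_value == pytest.approx(1 / math.comb(5, 2))

    def test_exact_p_single_best_of_ten(self):
        p = np.linspace(0.01, 0.9, 10)
        r = mean_rank_test(_gs(p), ["g000"])
        assert r.p_value == pytest.approx(0.1)

    def test_interleaved_set_is_not_significant(self):
        p = np.linspace(0.05, 0.95, 10)
        r = mean_rank_test(_gs(p), ["g000", "g003", "g006", "g009"])
        assert 0.3 < r.p_value < 0.9

    def test_matches_rank_sum_enumeration(self, rng):
        p = rng.uniform(size=12)
        members = ["g000", "g004", "g007", "g011"]
        r = mean_rank_test(_gs(p), members, exact_max=12)
        ranks = stats.rankdata(p)
        obs = ranks[[0, 4, 7, 11]].sum()
        sums = [ranks[list(c)].sum()
                for c in itertools.combinations(range(12), 4)]
        assert r.p_value == pytest.approx(np.mean([s <= obs for s in sums]))

    def test_set_equal_universe_is_error(self):
        with pytest.raises(ValueError):
            mean_rank_test(_gs([0.1, 0.2]), ["g000", "g001"])


class TestSigpathway:
    def test_q1_exhaustive_matches_brute_force(self, rng):
        ds = _ds(rng.normal(8, 2, size=(6, 8)))
        members = ["g000", "g002", "g004"]
        spec = MethodSpec("SIGPATHWAY_Q1", n_perm=1000, seed=0)
        r = sigpathway_test(ds, members, spec, "Q1")
        t = moderated_t(ds).t_mod
        obs = t[[0, 2, 4]].mean()
        null_means = np.array([t[list(c)].mean()
                               for c in itertools.combinations(range(6), 3)])
        # two-sided on the standardized mean == two-sided on the raw mean
        centered = np.abs(null_means - t.mean())
        expect = np.mean(centered >= abs(obs - t.mean()) - 1e-12)
        assert r.p_value == pytest.approx(expect)

    def test_q2_constant_expression_gives_p_one(self):
        ds = _ds(np.full((5, 8), 3.0))
        r = sigpathway_test(ds, ["g000", "g001"], MethodSpec("SIGPATHWAY_Q2"), "Q2")
        assert r.p_value == 1.0

    def test_q1_needs_background(self, tiny_ds):
        with pytest.raises(ValueError):
            sigpathway_test(tiny_ds, list(tiny_ds.feature_ids),
                            MethodSpec("SIGPATHWAY_Q1"), "Q1")


class TestGsaMaxmean:
    def test_maxmean_direct_formula(self):
        t = np.array([2.0, -1.0, 3.0])
        assert maxmean(t, np.array([0, 1, 2])) == pytest.approx(5 / 3)

    def test_maxmean_negative_trend_keeps_sign(self):
        t = np.array([-2.0, -2.0, -2.0])
        assert maxmean(t, np.array([0, 1, 2])) == pytest.approx(-2.0)

    def test_all_zero_scores_give_p_one(self):
        ds = _ds(np.full((10, 8), 5.0))
        r = gsa_maxmean_test(ds, ["g000", "g001", "g002"], MethodSpec("GSA", n_perm=50))
        assert r.p_value == 1.0 and r.statistic == 0.0

    def test_single_gene_set_is_error(self, tiny_ds):
        with pytest.raises(ValueError):
            gsa_maxmean_test(tiny_ds, ["g00"], MethodSpec("GSA"))


class TestPadog:
    def test_weight_formula_endpoints(self):
        col = GeneSetCollection(sets={
            "s1": ["a", "b"], "s2": ["a", "c"], "s3": ["a", "d"],
            "s4": ["a", "e"], "s5": ["a", "f"],
        })
        w = padog_weights(col)
        assert w["a"] == pytest.approx(1.0)        # f = 5 = f_max
        assert w["b"] == pytest.approx(2.0)        # f = 1 = f_min

    def test_flat_frequencies_give_unit_weights(self):
        col = GeneSetCollection(sets={"s1": ["a", "b"], "s2": ["c", "d"]})
        assert set(padog_weights(col).values()) == {1.0}

    def test_constant_data_gives_p_one(self):
        ds = _ds(np.full((8, 8), 2.0))
        col = GeneSetCollection(sets={
            "s1": ["g000", "g001", "g002"], "s2": ["g003", "g004", "g005"]})
        r = padog_test(ds, col, "s1", MethodSpec("PADOG", n_perm=20))
        assert r.p_value == 1.0

    def test_unknown_set_is_error(self, tiny_ds, small_collection):
        with pytest.raises(ValueError, match="not in the analyzed"):
            padog_test(tiny_ds, small_collection, "nope", MethodSpec("PADOG"))


class TestGage:
    def test_single_case_equals_single_comparison(self, rng):
        expr = rng.normal(8, 2, size=(30, 4))
        ds = ExpressionDataset(
            expr=expr, feature_ids=[f"g{i:03d}" for i in range(30)],
            sample_ids=list("abcd"), group=np.array([1, 0, 0, 0]))
        members = [f"g{i:03d}" for i in range(6)]
        r = gage_test(ds, members, MethodSpec("GAGE"))
        fc = expr[:, 0] - expr[:, 1:].mean(axis=1)
        ref = stats.ttest_ind(fc[:6], fc[6:], equal_var=False)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_comparisons_stouffer_scaling(self, rng):
        expr = rng.normal(8, 2, size=(30, 4))
        base = ExpressionDataset(
            expr=expr, feature_ids=[f"g{i:03d}" for i in range(30)],
            sample_ids=list("abcd"), group=np.array([1, 0, 0, 0]))
        members = [f"g{i:03d}" for i in range(6)]
        z1 = gage_test(base, members, MethodSpec("GAGE")).statistic
        # duplicate the case column 4 times: four identical comparisons
        expr4 = np.column_stack([expr[:, [0]]] * 4 + [expr[:, 1:]])
        ds4 = ExpressionDataset(
            expr=expr4, feature_ids=base.feature_ids,
            sample_ids=[f"s{i}" for i in range(7)],
            group=np.array([1, 1, 1, 1, 0, 0, 0]))
        z4 = gage_test(ds4, members, MethodSpec("GAGE")).statistic
        assert z4 == pytest.approx(z1 * 2.0, rel=1e-10)   # z * sqrt(4)

    def test_fisher_combination_option(self, rng):
        ds = _ds(rng.normal(8, 2, size=(30, 8)))
        members = [f"g{i:03d}" for i in range(6)]
        r = gage_test(ds, members, MethodSpec("GAGE", params={"combine": "fisher"}))
        assert 0 < r.p_value <= 1


class TestCamera:
    def test_independent_set_reduces_to_unadjusted_z(self, rng):
        ds = _ds(rng.normal(8, 2, size=(100, 12)))
        members = [f"g{i:03d}" for i in range(10)]
        r = camera_test(ds, members)
        t = moderated_t(ds).t_mod
        delta = t[:10].mean() - t[10:].mean()
        m = ds.expr[:100].copy()
        resid = ds.expr.copy()
        resid[:, :6] -= resid[:, :6].mean(1, keepdims=True)
        resid[:, 6:] -= resid[:, 6:].mean(1, keepdims=True)
        corr = np.corrcoef(resid[:10])
        rho = (corr.sum() - 10) / 90
        vif = 1 + 9 * rho
        expect = delta / np.sqrt(t.var(ddof=1) * (vif / 10 + 1 / 90))
        assert r.statistic == pytest.approx(expect, rel=1e-10)
        # with ~zero correlation the VIF is ~1
        assert abs(rho) < 0.15

    def test_perfect_correlation_inflates_by_set_size(self, rng):
        base = rng.normal(0, 1, size=12)
        noise = rng.normal(8, 2, size=(40, 12))
        expr = np.vstack([np.tile(base, (5, 1)) + 8.0, noise])
        ds = _ds(expr)
        r = camera_test(ds, [f"g{i:03d}" for i in range(5)])
        t = moderated_t(ds).t_mod
        delta = t[:5].mean() - t[5:].mean()
        # rho = 1 -> VIF = m = 5
        expect = delta / np.sqrt(t.var(ddof=1) * (5 / 5 + 1 / 40))
        assert r.statistic == pytest.approx(expect, rel=1e-6)

    def test_small_set_is_error(self, tiny_ds):
        with pytest.raises(ValueError):
            camera_test(tiny_ds, ["g00"])


class TestGlobaltest:
    def test_subset_moments_match_enumeration(self, rng):
        M = rng.standard_normal((4, 7))
        M -= M.mean(axis=1, keepdims=True)
        A = M.T @ M / 4
        qs = np.array([A[np.ix_(S, S)].sum()
                       for S in itertools.combinations(range(7), 3)])
        mu, var = _subset_quadratic_moments(A, 3)
        assert mu == pytest.approx(qs.mean())
        assert var == pytest.approx(qs.var())

    def test_constant_set_gives_p_one(self):
        ds = _ds(np.vstack([np.full((3, 8), 4.0), np.random.default_rng(0).normal(size=(3, 8))]))
        r = globaltest_test(ds, ["g000", "g001", "g002"])
        assert r.p_value == 1.0 and r.statistic == 0.0

    def test_separating_gene_has_extreme_permutation_p(self):
        rng = np.random.default_rng(1)
        expr = rng.normal(8, 2, size=(20, 12))
        expr[0, :6] += 50.0
        ds = _ds(expr)
        r = globaltest_test(ds, ["g000"], MethodSpec("GLOBALTEST", n_perm=500, seed=0),
                            pvalue="permutation")
        # the complement labelling ties the observed Q exactly, so the
        # smallest reachable p is about 2/(B+1)
        assert r.p_value <= 3 / 501

    def test_exact_enumeration_used_for_small_designs(self):
        # n=12 -> C(12,6)=924 labelings: the default p must equal the
        # exhaustively enumerated permutation p
        rng = np.random.default_rng(3)
        expr = rng.normal(8, 2, size=(30, 12))
        expr[:5, :6] += 0.8
        ds = _ds(expr)
        members = [f"g{i:03d}" for i in range(5)]
        r = globaltest_test(ds, members)
        X = ds.expr[:5]
        X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=0, keepdims=True)
        qs = np.array([np.sum(X[:, list(S)].sum(axis=1) ** 2) / 5
                       for S in itertools.combinations(range(12), 6)])
        q_obs = np.sum(X[:, :6].sum(axis=1) ** 2) / 5
        assert r.p_value == pytest.approx(np.mean(qs >= q_obs - 1e-9))

    def test_moment_p_close_to_permutation_p(self):
        # benchmark-scale design (10 vs 10) where the Satterthwaite path
        # is active
        rng = np.random.default_rng(3)
        expr = rng.normal(8, 2, size=(60, 20))
        expr[:8, :10] += 0.6         # modest real signal
        ds = _ds(expr)
        members = [f"g{i:03d}" for i in range(8)]
        pm = globaltest_test(ds, members).p_value
        pp = globaltest_test(
            ds, members, MethodSpec("GLOBALTEST", n_perm=10000, seed=0),
            pvalue="permutation").p_value
        assert pm == pytest.approx(pp, abs=0.02)


class TestGseaEs:
    def test_hand_computed_running_sum(self):
        # r = [4,3,2,1], set at the top two positions, weight 1
        es = gsea_es(np.array([4.0, 3.0, 2.0, 1.0]), [0, 1], weight_exp=1.0)
        assert es == pytest.approx(1.0)

    def test_top_block_attains_unit_score(self, rng):
        r = np.sort(rng.uniform(1, 5, size=20))[::-1]
        assert gsea_es(r, list(range(5))) == pytest.approx(1.0)

    def test_weight_zero_is_classic_ks(self, rng):
        r = np.sort(rng.normal(size=30))[::-1]
        pos = [2, 5, 11, 17, 25]
        es = gsea_es(r, pos, weight_exp=0.0)
        # independent oracle: full running sum with uniform increments
        hit = np.zeros(30, dtype=bool)
        hit[pos] = True
        run = np.cumsum(np.where(hit, 1 / 5, -1 / 25))
        assert es == pytest.approx(run[np.argmax(np.abs(run))])

    def test_matches_full_running_sum_oracle(self, rng):
        for _ in range(25):
            g = int(rng.integers(8, 40))
            m = int(rng.integers(2, g - 1))
            r = np.sort(rng.normal(size=g))[::-1]
            pos = rng.choice(g, size=m, replace=False)
            hit = np.zeros(g, dtype=bool)
            hit[pos] = True
            w = np.abs(r) * hit
            if w.sum() == 0:
                continue
            run = np.cumsum(np.where(hit, np.abs(r) / w.sum(), -1 / (g - m)))
            expect = run.max() if run.max() >= -run.min() - 1e-9 else run.min()
            assert gsea_es(r, pos) == pytest.approx(expect)

    def test_zero_weight_set_is_error(self):
        with pytest.raises(ValueError):
            gsea_es(np.array([1.0, 0.5, 0.0, 0.0]), [2, 3], weight_exp=1.0)


class TestGseap:
    def test_exhaustive_gene_sampling_matches_enumeration(self, rng):
        ds = _ds(rng.normal(8, 2, size=(6, 8)))
        members = ["g001", "g003", "g004"]
        r = gseap_test(ds, members, MethodSpec("GSEAP", n_perm=1000, seed=0))
        t = moderated_t(ds).t_mod
        order = np.argsort(-t, kind="stable")
        rs = t[order]
        inv = np.empty(6, dtype=int)
        inv[order] = np.arange(6)
        obs = gsea_es(rs, inv[[1, 3, 4]])
        null = np.array([gsea_es(rs, inv[list(c)])
                         for c in itertools.combinations(range(6), 3)])
        pool = null[null >= 0] if obs >= 0 else null[null <= 0]
        cnt = (pool >= obs).sum() if obs >= 0 else (pool <= obs).sum()
        assert r.statistic == pytest.approx(obs)
        assert r.p_value == pytest.approx(cnt / pool.size)

    def test_constant_data_guard(self):
        ds = _ds(np.full((8, 8), 1.0))
        r = gseap_test(ds, ["g000", "g001"], MethodSpec("GSEAP", n_perm=50))
        assert r.p_value == 1.0
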