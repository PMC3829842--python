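"""Functional class scoring statistics.

Competitive gene-sampling tests (MRGSE, SIGPATHWAY-Q1, GAGE, CAMERA's
parametric analogue) and self-contained sample-permutation tests (SAFE,
SIGPATHWAY-Q2, GSA maxmean, PADOG) plus GLOBALTEST's score test.  The
permutation-based tests share one engine: a moderated-t matrix recomputed
under phenotype relabelings (see ``_engine``).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
from scipy import stats

from ..datamodel import ExpressionDataset, GeneSetCollection, MethodResult
from ..genestats import GeneStats
from ..resampling import sample_random_sets
from ._engine import DatasetStats
from ._util import set_indices, tail_p

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MRGSE — mean-rank gene set enrichment (Wilcoxon rank-sum on p-value ranks)


def mean_rank_test(gs: GeneStats, set_genes: list[str],
                   exact_max: int = 20) -> MethodResult:
    """Wilcoxon rank-sum of the set's genes vs the background after ranking
    all genes by moderated-t p-value; one-sided toward smaller ranks (more
    significant).  Exact enumeration for universes of <= ``exact_max`` genes,
    otherwise normal approximation with continuity correction."""
    idx = set_indices(gs.gene_ids, set_genes)
    G = len(gs.gene_ids)
    mask = np.zeros(G, dtype=bool)
    mask[idx] = True
    if mask.all():
        raise ValueError("competitive test needs a non-empty background")
    ranks = stats.rankdata(gs.p)
    method = "exact" if G <= exact_max else "asymptotic"
    res = stats.mannwhitneyu(ranks[mask], ranks[~mask], alternative="less",
                             method=method, use_continuity=True)
    return MethodResult(set_id="", size_used=int(mask.sum()),
                        statistic=float(res.statistic),
                        p_value=float(res.pvalue), method_id="MRGSE")


# ---------------------------------------------------------------------------
# SIGPATHWAY — standardized mean of gene-level scores, two nulls


def _std_mean(t: np.ndarray, idx: np.ndarray) -> float:
    m = len(idx)
    sd = t.std(ddof=1)
    if sd == 0:
        return 0.0
    return float((t[idx].mean() - t.mean()) / (sd / np.sqrt(m)))


def sigpathway_test(ds: ExpressionDataset, set_genes: list[str], spec,
                    hypothesis: str, cache: DatasetStats | None = None) -> MethodResult:
    """Q1: competitive null by random same-size gene sets.
    Q2: self-contained null by sample permutation."""
    cache = cache or DatasetStats(ds)
    t = cache.gene_stats().t_mod
    idx = set_indices(ds.feature_ids, set_genes)
    G, m = len(t), len(idx)
    if hypothesis == "Q1":
        if m == G:
            raise ValueError("competitive test needs a non-empty background")
        obs = _std_mean(t, idx)
        rng = np.random.default_rng(spec.seed)
        bank, exhaustive = sample_random_sets(G, m, spec.n_perm, rng)
        sd = t.std(ddof=1)
        if sd == 0:
            return MethodResult("", m, 0.0, 1.0, "SIGPATHWAY_Q1")
        nulls = (t[bank].mean(axis=1) - t.mean()) / (sd / np.sqrt(m))
        p = tail_p(obs, nulls, "two-sided", include_observed=exhaustive)
        return MethodResult("", m, obs, p, "SIGPATHWAY_Q1")
    if hypothesis == "Q2":
        T, exhaustive = cache.perm_t(spec.n_perm, spec.seed)
        obs = _std_mean(t, idx)
        sds = T.std(axis=0, ddof=1)
        means = T.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            nulls = (T[idx].mean(axis=0) - means) / (sds / np.sqrt(m))
        nulls = np.where(np.isfinite(nulls), nulls, 0.0)
        if np.all(nulls == 0.0) and obs == 0.0:
            return MethodResult("", m, 0.0, 1.0, "SIGPATHWAY_Q2")
        p = tail_p(obs, nulls, "two-sided", include_observed=False)
        return MethodResult("", m, obs, p, "SIGPATHWAY_Q2")
    raise ValueError(f"unknown hypothesis {hypothesis!r}")


# ---------------------------------------------------------------------------
# SAFE — Wilcoxon rank-sum of |t| ranks, sample-permutation null


def safe_test(ds: ExpressionDataset, set_genes: list[str], spec,
              cache: DatasetStats | None = None) -> MethodResult:
    cache = cache or DatasetStats(ds)
    t = cache.gene_stats().t_mod
    idx = set_indices(ds.feature_ids, set_genes)
    if len(idx) == len(t):
        raise ValueError("set equals the universe; no background for SAFE")
    obs = float(stats.rankdata(np.abs(t))[idx].sum())
    T, exhaustive = cache.perm_t(spec.n_perm, spec.seed)
    null_ranks = stats.rankdata(np.abs(T), axis=0)
    nulls = null_ranks[idx].sum(axis=0)
    p = tail_p(obs, nulls, "greater", include_observed=False)
    return MethodResult("", len(idx), obs, p, "SAFE")


# ---------------------------------------------------------------------------
# GSA — restandardized maxmean statistic, sample-permutation null


def maxmean(t: np.ndarray, idx: np.ndarray) -> float:
    """Signed maxmean: the larger in magnitude of the mean positive part
    and the mean negative part of the set's gene scores."""
    m = len(idx)
    sp = np.maximum(t[idx], 0.0).sum() / m
    sn = np.maximum(-t[idx], 0.0).sum() / m
    return float(sp if sp >= sn else -sn)


def _maxmean_bank(t_cols: np.ndarray, bank: np.ndarray) -> np.ndarray:
    """maxmean of each bank row (random set) for each column of t_cols.

    t_cols: (G, B); bank: (R, m).  Returns (R, B).
    """
    pos = np.maximum(t_cols, 0.0)
    neg = np.maximum(-t_cols, 0.0)
    m = bank.shape[1]
    sp = pos[bank].sum(axis=1) / m    # (R, B)
    sn = neg[bank].sum(axis=1) / m
    return np.where(sp >= sn, sp, -sn)


def gsa_maxmean_test(ds: ExpressionDataset, set_genes: list[str], spec,
                     cache: DatasetStats | None = None,
                     n_restand: int = 100) -> MethodResult:
    """GSA: maxmean restandardized against size-matched random gene sets,
    significance by sample permutation of the restandardized statistic."""
    cache = cache or DatasetStats(ds)
    t = cache.gene_stats().t_mod
    idx = set_indices(ds.feature_ids, set_genes)
    m = len(idx)
    if m < 2:
        raise ValueError("GSA requires sets of >= 2 genes")
    rng = np.random.default_rng(spec.seed)
    bank, _ = sample_random_sets(len(t), m, n_restand, rng)
    T, exhaustive = cache.perm_t(spec.n_perm, spec.seed)
    cols = np.column_stack([t, T])          # observed first
    mm_set = np.array([maxmean(cols[:, j], idx) for j in range(cols.shape[1])])
    ref = _maxmean_bank(cols, bank)         # (R, 1+B)
    mu, sd = ref.mean(axis=0), ref.std(axis=0, ddof=1)
    if np.all(sd == 0):
        return MethodResult("", m, 0.0, 1.0, "GSA")
    sd = np.where(sd == 0, 1.0, sd)
    z = (mm_set - mu) / sd
    p = tail_p(z[0], z[1:], "two-sided", include_observed=False)
    return MethodResult("", m, float(z[0]), p, "GSA")


# ---------------------------------------------------------------------------
# PADOG — down-weighted mean |t|, per-permutation standardization


def padog_weights(collection: GeneSetCollection) -> dict[str, float]:
    """w = 1 + sqrt((f_max - f) / (f_max - f_min)) with f the number of
    analyzed sets containing the gene; all 1 when frequencies are flat."""
    freq = collection.gene_frequencies()
    fmin, fmax = min(freq.values()), max(freq.values())
    if fmax == fmin:
        return {g: 1.0 for g in freq}
    return {g: 1.0 + np.sqrt((fmax - f) / (fmax - fmin)) for g, f in freq.items()}


def run_padog(ds: ExpressionDataset, collection: GeneSetCollection, spec,
              cache: DatasetStats) -> list[MethodResult]:
    """PADOG over a whole collection (the weights require it)."""
    t = cache.gene_stats().t_mod
    weights = padog_weights(collection)
    wvec = np.zeros(len(ds.feature_ids))
    fidx = {f: i for i, f in enumerate(ds.feature_ids)}
    for g, w in weights.items():
        j = fidx.get(g)
        if j is not None:
            wvec[j] = w
    T, exhaustive = cache.perm_t(spec.n_perm, spec.seed)
    indic = collection.indicator(ds.feature_ids)
    sizes = indic.sum(axis=1)
    if np.any(sizes < 1):
        raise ValueError("a gene set has no genes in the dataset")
    obs_scores = indic @ (np.abs(t) * wvec) / sizes                 # (S,)
    null_scores = indic @ (np.abs(T) * wvec[:, None]) / sizes[:, None]  # (S, B)

    def _std(a, axis=0):
        mu = a.mean(axis=axis, keepdims=True)
        sd = a.std(axis=axis, ddof=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        return (a - mu) / sd

    obs_std = _std(obs_scores[:, None]).ravel()
    null_std = _std(null_scores, axis=0)
    out = []
    for i, sid in enumerate(collection.set_ids):
        if np.all(null_scores[i] == obs_scores[i]):
            p = 1.0
        else:
            p = tail_p(obs_std[i], null_std[i], "greater", include_observed=False)
        out.append(MethodResult(sid, int(sizes[i]), float(obs_std[i]), p, "PADOG"))
    return out


def padog_test(ds: ExpressionDataset, collection: GeneSetCollection,
               set_id: str, spec, cache: DatasetStats | None = None) -> MethodResult:
    if set_id not in collection:
        raise ValueError(f"set {set_id!r} not in the analyzed collection")
    cache = cache or DatasetStats(ds)
    for r in run_padog(ds, collection, spec, cache):
        if r.set_id == set_id:
            return r
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# GAGE — fold-change shift vs background, one-on-group comparisons combined


def gage_test(ds: ExpressionDataset, set_genes: list[str], spec,
              cache: DatasetStats | None = None) -> MethodResult:
    """For each case sample, a two-sample t between the set's and the
    background's per-gene fold changes vs the control-group mean; the
    per-case p-values are combined assuming independence (Stouffer on
    signed z by default, Fisher optionally via ``spec.params['combine']``).
    """
    idx = set_indices(ds.feature_ids, set_genes)
    G = ds.n_features
    if len(idx) == G:
        raise ValueError("GAGE needs a non-empty background")
    combine = getattr(spec, "params", {}).get("combine", "stouffer")
    ctrl_mean = ds.expr[:, ds.control_idx].mean(axis=1)
    fc = ds.expr[:, ds.case_idx] - ctrl_mean[:, None]     # (G, k)
    mask = np.zeros(G, dtype=bool)
    mask[idx] = True
    tt = stats.ttest_ind(fc[mask], fc[~mask], axis=0, equal_var=False)
    tvals, pvals = np.atleast_1d(tt.statistic), np.atleast_1d(tt.pvalue)
    ok = np.isfinite(tvals)
    tvals, pvals = tvals[ok], np.clip(pvals[ok], np.finfo(float).tiny, 1.0)
    if tvals.size == 0:
        return MethodResult("", len(idx), 0.0, 1.0, "GAGE")
    if combine == "fisher":
        chi2 = -2.0 * np.log(pvals).sum()
        p = float(stats.chi2.sf(chi2, 2 * pvals.size))
        return MethodResult("", len(idx), float(chi2), p, "GAGE")
    z = np.sign(tvals) * stats.norm.isf(pvals / 2.0)
    zc = float(z.sum() / np.sqrt(z.size))
    p = float(2.0 * stats.norm.sf(abs(zc)))
    return MethodResult("", len(idx), zc, p, "GAGE")


# ---------------------------------------------------------------------------
# CAMERA — competitive test with variance-inflation correlation adjustment


def camera_test(ds: ExpressionDataset, set_genes: list[str], spec=None,
                cache: DatasetStats | None = None) -> MethodResult:
    """Standardized mean-difference of moderated t (set vs background),
    with the set term inflated by VIF = 1 + (m-1)*rho_bar, rho_bar being
    the mean inter-gene correlation of the set's residual expression."""
    cache = cache or DatasetStats(ds)
    t = cache.gene_stats().t_mod
    idx = set_indices(ds.feature_ids, set_genes)
    G, m = len(t), len(idx)
    if m < 2:
        raise ValueError("CAMERA requires sets of >= 2 genes")
    if m == G:
        raise ValueError("CAMERA needs a non-empty background")
    resid = ds.expr.copy()
    for grp in (ds.case_idx, ds.control_idx):
        resid[:, grp] -= resid[:, grp].mean(axis=1, keepdims=True)
    sub = resid[idx]
    sds = sub.std(axis=1)
    keep = sds > 0
    if keep.sum() >= 2:
        corr = np.corrcoef(sub[keep])
        rho = float((corr.sum() - np.trace(corr)) / (keep.sum() * (keep.sum() - 1)))
    else:
        rho = 0.0
    vif = max(1.0 + (m - 1) * rho, np.finfo(float).eps)
    mask = np.zeros(G, dtype=bool)
    mask[idx] = True
    delta = t[mask].mean() - t[~mask].mean()
    s2 = t.var(ddof=1)
    if s2 == 0:
        return MethodResult("", m, 0.0, 1.0, "CAMERA")
    z = delta / np.sqrt(s2 * (vif / m + 1.0 / (G - m)))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MethodResult("", m, float(z), p, "CAMERA")


# ---------------------------------------------------------------------------
# GLOBALTEST — score test for association of set expression with phenotype


def globaltest_test(ds: ExpressionDataset, set_genes: list[str], spec=None,
                    cache: DatasetStats | None = None,
                    pvalue: str = "moment") -> MethodResult:
    """Score statistic Q = ||X u||^2 / m with X the row-standardized set
    submatrix and u the centered 0/1 phenotype.  The default p-value
    matches a scaled chi-square (Satterthwaite) to the *exact* first two
    moments of Q under phenotype permutation, computed in closed form
    from A = X'X/m via the subset representation Q = 1_S' A 1_S (S the
    random case subset); ``pvalue='permutation'`` uses sample permutation
    instead.
    """
    idx = set_indices(ds.feature_ids, set_genes)
    y = ds.group.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("constant phenotype")
    X = ds.expr[idx].astype(float)
    sds = X.std(axis=1, ddof=0)
    keep = sds > 0
    if not keep.any():
        return MethodResult("", len(idx), 0.0, 1.0, "GLOBALTEST")
    if (~keep).any():
        log.info("GLOBALTEST: dropped %d constant gene(s)", (~keep).sum())
    X = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sds[keep][:, None]
    m = X.shape[0]
    n = ds.n_samples
    u = y - y.mean()
    Q = float(np.sum((X @ u) ** 2) / m)
    n1 = int(y.sum())
    n0 = n - n1
    if pvalue == "permutation":
        n_perm = spec.n_perm if spec is not None else 1000
        seed = spec.seed if spec is not None else 0
        rng = np.random.default_rng(seed)
        nulls = np.empty(n_perm)
        for b in range(n_perm):
            nulls[b] = np.sum((X @ rng.permutation(u)) ** 2) / m
        p = tail_p(Q, nulls, "greater", include_observed=False)
        return MethodResult("", len(idx), Q, p, "GLOBALTEST")
    A = X.T @ X / m                      # n x n; A @ 1 = 0 since rows centered
    from math import comb as _comb
    if _comb(n, n1) <= 20000:
        # small designs: the case-subset space is enumerable, so use the
        # exact permutation null instead of its chi-square approximation
        subsets = np.array(list(itertools.combinations(range(n), n1)))
        onehot = np.zeros((len(subsets), n))
        np.put_along_axis(onehot, subsets, 1.0, axis=1)
        qs = np.einsum("si,ij,sj->s", onehot, A, onehot)
        p = float(np.mean(qs >= Q - 1e-12 * max(1.0, abs(Q))))
        return MethodResult("", len(idx), Q, p, "GLOBALTEST")
    mu, var = _subset_quadratic_moments(A, n1)
    if mu <= 0 or var <= 0:
        return MethodResult("", len(idx), Q, 1.0, "GLOBALTEST")
    g = var / (2.0 * mu)
    nu = 2.0 * mu ** 2 / var
    p = float(stats.chi2.sf(Q / g, nu))
    return MethodResult("", len(idx), Q, p, "GLOBALTEST")


def _subset_quadratic_moments(A: np.ndarray, k: int) -> tuple[float, float]:
    """Exact mean and variance of Q(S) = 1_S' A 1_S over uniform random
    subsets S of size k of {1..n} (A symmetric).

    Because A annihilates the all-ones vector here, Q(S) equals the
    centered-label quadratic form u'Au, so these are the exact phenotype-
    permutation moments of the GLOBALTEST statistic.
    """
    n = A.shape[0]
    diag = np.diag(A)
    a1 = diag.sum()                       # tr A
    a2d = np.sum(diag ** 2)
    r = A.sum(axis=1) - diag              # off-diagonal row sums
    s_off = r.sum()
    a_off2 = np.sum(A ** 2) - a2d
    d1 = np.sum(diag * r)
    sum_r2 = np.sum(r ** 2)

    def falling(k_, n_, terms):
        num = den = 1.0
        for j in range(terms):
            num *= k_ - j
            den *= n_ - j
        return num / den

    p1, p2, p3, p4 = (falling(k, n, j) for j in (1, 2, 3, 4))
    mean = p1 * a1 + p2 * s_off
    e2 = (
        p1 * a2d + p2 * (a1 ** 2 - a2d)                       # diag x diag
        + 2.0 * (p2 * 2.0 * d1 + p3 * (a1 * s_off - 2.0 * d1))  # diag x off
        + p2 * 2.0 * a_off2
        + p3 * 4.0 * (sum_r2 - a_off2)
        + p4 * (s_off ** 2 + 2.0 * a_off2 - 4.0 * sum_r2)     # off x off
    )
    return float(mean), float(e2 - mean ** 2)
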