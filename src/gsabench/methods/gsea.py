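"""Weighted Kolmogorov-Smirnov enrichment score and the GSEA / GSEAP tests.

The enrichment score walks the gene list sorted by a per-gene association
statistic: hits (set members) advance the running sum proportionally to
|stat|^weight_exp (normalized over the set), misses retreat by 1/(G - m).
ES is the signed maximum deviation from zero.  GSEA draws its null from
sample permutation (re-ranking under relabeled phenotypes); GSEAP keeps
the observed ranking and draws random same-size gene sets instead, which
is what makes it applicable to arbitrary pre-ranked lists (e.g. paired
designs) at the price of a competitive, gene-sampling null.

The running sum between consecutive hits is linear, so its extrema occur
immediately after a hit or immediately before the next one; ES is
therefore computed from the m hit positions alone in O(m log m).
"""

from __future__ import annotations

import numpy as np

from ..datamodel import ExpressionDataset, GeneSetCollection, MethodResult
from ..resampling import sample_random_sets
from ._engine import DatasetStats
from ._util import set_indices, tail_p


def _es_candidates(w_sorted: np.ndarray, positions: np.ndarray, n_miss: int):
    """Running-sum values right after and right before each hit.

    ``positions``: (..., m) 0-based hit positions in the sorted list, sorted
    ascending along the last axis.  Returns (after, before), each (..., m).
    Raises if a set's total hit weight is zero.
    """
    wq = w_sorted[positions]
    denom = wq.sum(axis=-1, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("all set genes have zero-weight statistics")
    H = np.cumsum(wq, axis=-1) / denom
    j = np.arange(positions.shape[-1])
    miss_rate = 1.0 / n_miss if n_miss > 0 else 0.0
    misses_before = (positions - j) * miss_rate
    after = H - misses_before
    before = (H - wq / denom) - misses_before
    return after, before


def _signed_max(after: np.ndarray, before: np.ndarray) -> np.ndarray:
    # extreme deviation of the running sum; exact ties resolve positive
    cand = np.concatenate([after, before], axis=-1)
    mx = cand.max(axis=-1)
    mn = cand.min(axis=-1)
    tol = 1e-12 * (np.abs(mx) + np.abs(mn))
    return np.where(mx >= -mn - tol, mx, mn)


def gsea_es(ranked_stats: np.ndarray, set_positions, weight_exp: float = 1.0) -> float:
    """Enrichment score for one set on a descending-sorted statistic vector.

    ``set_positions`` are the 0-based positions of the set's genes in the
    sorted list.  ``weight_exp=0`` gives the classic unweighted KS statistic.
    """
    stats_sorted = np.asarray(ranked_stats, dtype=float)
    pos = np.sort(np.asarray(set_positions, dtype=np.intp))
    G, m = len(stats_sorted), len(pos)
    if m == 0 or m >= G:
        raise ValueError("set must be a proper non-empty subset of the universe")
    if weight_exp < 0:
        raise ValueError("weight_exp must be >= 0")
    w = np.abs(stats_sorted) ** weight_exp
    after, before = _es_candidates(w, pos, G - m)
    return float(_signed_max(after, before))


def _es_for_sets(stats_vec: np.ndarray, set_idx_list: list[np.ndarray],
                 weight_exp: float) -> np.ndarray:
    """ES of several sets against one statistic vector (positions derived
    from a fresh descending sort)."""
    order = np.argsort(-stats_vec, kind="stable")
    pos_of = np.empty(len(stats_vec), dtype=np.intp)
    pos_of[order] = np.arange(len(stats_vec))
    w_sorted = np.abs(stats_vec[order])
    if weight_exp != 1.0:
        w_sorted = w_sorted ** weight_exp
    out = np.empty(len(set_idx_list))
    for i, idx in enumerate(set_idx_list):
        pos = np.sort(pos_of[idx])
        after, before = _es_candidates(w_sorted, pos, len(stats_vec) - len(idx))
        out[i] = _signed_max(after, before)
    return out


def _signed_pool_p(obs: float, nulls: np.ndarray) -> float:
    """GSEA convention: positive and negative null ES pooled separately."""
    if obs >= 0:
        pool = nulls[nulls >= 0]
        b = np.sum(pool >= obs)
    else:
        pool = nulls[nulls <= 0]
        b = np.sum(pool <= obs)
    return float((b + 1) / (pool.size + 1))


def gsea_test(ds: ExpressionDataset, set_genes: list[str], spec,
              cache: DatasetStats | None = None,
              weight_exp: float = 1.0) -> MethodResult:
    """GSEA: observed ES vs ES under sample permutation."""
    cache = cache or DatasetStats(ds)
    t = cache.gene_stats().t_mod
    idx = set_indices(ds.feature_ids, set_genes)
    if np.all(t == 0):
        return MethodResult("", len(idx), 0.0, 1.0, "GSEA")
    T, _ = cache.perm_t(spec.n_perm, spec.seed)
    obs = _es_for_sets(t, [idx], weight_exp)[0]
    nulls = np.empty(T.shape[1])
    for b in range(T.shape[1]):
        col = T[:, b]
        if np.all(col == 0):
            nulls[b] = 0.0
        else:
            nulls[b] = _es_for_sets(col, [idx], weight_exp)[0]
    return MethodResult("", len(idx), float(obs), _signed_pool_p(obs, nulls), "GSEA")


def gseap_test(ds: ExpressionDataset, set_genes: list[str], spec,
               cache: DatasetStats | None = None,
               weight_exp: float = 1.0) -> MethodResult:
    """GSEA pre-ranked: the observed moderated-t ranking is fixed and the
    null ES comes from random same-size gene sets (gene sampling)."""
    cache = cache or DatasetStats(ds)
    t = cache.gene_stats().t_mod
    idx = set_indices(ds.feature_ids, set_genes)
    G, m = len(t), len(idx)
    if np.all(t == 0):
        return MethodResult("", m, 0.0, 1.0, "GSEAP")
    order = np.argsort(-t, kind="stable")
    pos_of = np.empty(G, dtype=np.intp)
    pos_of[order] = np.arange(G)
    w_sorted = np.abs(t[order]) ** weight_exp
    after, before = _es_candidates(w_sorted, np.sort(pos_of[idx]), G - m)
    obs = float(_signed_max(after, before))
    rng = np.random.default_rng(spec.seed)
    bank, exhaustive = sample_random_sets(G, m, spec.n_perm, rng)
    pos_bank = np.sort(pos_of[bank], axis=1)
    keep = w_sorted[pos_bank].sum(axis=1) > 0
    a, b = _es_candidates(w_sorted, pos_bank[keep], G - m)
    nulls = _signed_max(a, b)
    if exhaustive:
        pool = nulls[nulls >= 0] if obs >= 0 else nulls[nulls <= 0]
        cnt = np.sum(pool >= obs) if obs >= 0 else np.sum(pool <= obs)
        p = float(cnt / pool.size) if pool.size else 1.0
    else:
        p = _signed_pool_p(obs, nulls)
    return MethodResult("", m, obs, p, "GSEAP")
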