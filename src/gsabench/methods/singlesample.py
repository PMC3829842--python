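"""Single-sample pathway scoring (PLAGE, ZSCORE, SSGSEA, GSVA).

Each method reduces a gene set's expression submatrix to one activity
score per sample; association with the phenotype is then inferred
downstream with a paired/unpaired moderated t-test across the per-set
score vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..datamodel import ExpressionDataset, GeneSetCollection, MethodResult
from ..genestats import moderated_t
from ._util import set_indices

log = logging.getLogger(__name__)


def _standardized_rows(ds: ExpressionDataset, idx: np.ndarray,
                       label: str) -> np.ndarray:
    """Row-standardized (mean 0, sd 1) set submatrix; constant genes are
    dropped with a warning, and an all-constant set is an error."""
    X = ds.expr[idx].astype(float)
    sds = X.std(axis=1, ddof=0)
    keep = sds > 0
    if not keep.any():
        raise ValueError(f"{label}: all set genes constant across samples")
    if (~keep).any():
        log.warning("%s: dropped %d zero-variance gene(s)", label, (~keep).sum())
    X = X[keep]
    return (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=0, keepdims=True)


def plage_scores(ds: ExpressionDataset, set_genes: list[str]) -> np.ndarray:
    """SVD metagene: samples projected on the first principal axis of the
    row-standardized set submatrix (first right singular vector scaled by
    its singular value).  The sign is fixed so the score correlates
    non-negatively with the set's mean standardized profile."""
    idx = set_indices(ds.feature_ids, set_genes)
    Z = _standardized_rows(ds, idx, "PLAGE")
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    scores = s[0] * vt[0]
    ref = Z.mean(axis=0)
    if float(scores @ ref) < 0:
        scores = -scores
    return scores


def zscore_scores(ds: ExpressionDataset, set_genes: list[str]) -> np.ndarray:
    """Combined z-score: sum of the set's standardized expression values in
    each sample divided by sqrt(m)."""
    idx = set_indices(ds.feature_ids, set_genes)
    Z = _standardized_rows(ds, idx, "ZSCORE")
    return Z.sum(axis=0) / np.sqrt(Z.shape[0])


def ssgsea_scores(ds: ExpressionDataset, set_genes: list[str],
                  tau: float = 0.25, normalize: bool = True) -> np.ndarray:
    """Rank-based single-sample enrichment: in each sample, the integrated
    difference between the rank^tau-weighted ECDF of the set genes and the
    unweighted ECDF of the background, walking the expression-sorted list.
    When ``normalize``, scores are scaled by their range across samples."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    idx = set_indices(ds.feature_ids, set_genes)
    G = ds.n_features
    m = len(idx)
    if m >= G:
        raise ValueError("ssGSEA needs a non-empty background")
    mask = np.zeros(G, dtype=bool)
    mask[idx] = True
    n = ds.n_samples
    out = np.empty(n)
    for s in range(n):
        x = ds.expr[:, s]
        ranks = stats.rankdata(x)               # highest expression -> rank G
        order = np.argsort(-x, kind="stable")
        hit = mask[order]
        w = ranks[order] ** tau
        win = np.where(hit, w, 0.0)
        cum_in = np.cumsum(win) / win.sum()
        cum_out = np.cumsum(~hit) / (G - m)
        out[s] = np.sum(cum_in - cum_out)
    if normalize:
        rng_ = out.max() - out.min()
        if rng_ > 0:
            out = out / rng_
    return out


def gsva_kernel_cdf(expr_row: np.ndarray, bandwidth_factor: float = 4.0) -> np.ndarray:
    """Gaussian-kernel CDF estimate of one gene's expression across samples
    (bandwidth sd / bandwidth_factor); constant genes map to 0.5."""
    x = np.asarray(expr_row, dtype=float)
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    if sd == 0:
        return np.full_like(x, 0.5)
    h = sd / bandwidth_factor
    return stats.norm.cdf((x[:, None] - x[None, :]) / h).mean(axis=1)


def gsva_scores(ds: ExpressionDataset, set_genes: list[str]) -> np.ndarray:
    """GSVA-style scores: expression mapped through a per-gene Gaussian
    kernel CDF, then a weighted KS running statistic per sample over genes
    ranked by the transformed values; score = max positive deviation minus
    max negative deviation."""
    if ds.n_samples < 3:
        raise ValueError("GSVA requires >= 3 samples")
    idx = set_indices(ds.feature_ids, set_genes)
    G = ds.n_features
    m = len(idx)
    if m >= G:
        raise ValueError("GSVA needs a non-empty background")
    X = ds.expr
    sd = X.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        log.info("GSVA: %d constant gene(s) mapped to 0.5", const.sum())
    h = np.where(const, 1.0, sd) / 4.0
    F = stats.norm.cdf(
        (X[:, :, None] - X[:, None, :]) / h[:, None, None]
    ).mean(axis=2)
    F[const] = 0.5
    mask = np.zeros(G, dtype=bool)
    mask[idx] = True
    out = np.empty(ds.n_samples)
    for s in range(ds.n_samples):
        f = F[:, s]
        order = np.argsort(-f, kind="stable")
        hit = mask[order]
        w = f[order]
        win = np.where(hit, w, 0.0)
        tot = win.sum()
        if tot == 0:
            out[s] = 0.0
            continue
        running = np.cumsum(win / tot - (~hit) / (G - m))
        out[s] = max(running.max(), 0.0) + min(running.min(), 0.0)
    return out


@dataclass
class SampleScoreMatrix:
    """set x sample single-sample pathway scores for one method."""

    method_id: str
    set_ids: list[str]
    sizes: list[int]
    scores: np.ndarray          # (n_sets, n_samples)

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite single-sample scores")


_SCORE_FUNS = {
    "PLAGE": plage_scores,
    "ZSCORE": zscore_scores,
    "SSGSEA": ssgsea_scores,
    "GSVA": gsva_scores,
}


def score_matrix(method_id: str, ds: ExpressionDataset,
                 collection: GeneSetCollection) -> SampleScoreMatrix:
    fun = _SCORE_FUNS[method_id]
    rows, sids, sizes = [], [], []
    for sid, genes in collection.sets.items():
        idx = set_indices(ds.feature_ids, genes)
        rows.append(fun(ds, genes))
        sids.append(sid)
        sizes.append(len(idx))
    return SampleScoreMatrix(method_id, sids, sizes, np.vstack(rows))


def ss_association_test(scores: SampleScoreMatrix,
                        ds: ExpressionDataset) -> list[MethodResult]:
    """Moderated t of each set's score vector against the phenotype
    (paired when the dataset is paired).  With a single set the
    empirical-Bayes fit is not identifiable, so the ordinary t is used."""
    pseudo = ExpressionDataset(
        expr=scores.scores,
        feature_ids=scores.set_ids,
        sample_ids=ds.sample_ids,
        group=ds.group,
        block=ds.block,
        name=f"{ds.name}:{scores.method_id}-scores",
    )
    if len(scores.set_ids) == 1:
        log.info("%s: single set; falling back to ordinary t", scores.method_id)
        gs = moderated_t(pseudo, df_prior=0)
    else:
        gs = moderated_t(pseudo)
    return [
        MethodResult(sid, scores.sizes[i], float(gs.t_mod[i]),
                     float(gs.p[i]), scores.method_id)
        for i, sid in enumerate(scores.set_ids)
    ]


def run_single_sample(method_id: str, ds: ExpressionDataset,
                      collection: GeneSetCollection) -> list[MethodResult]:
    return ss_association_test(score_matrix(method_id, ds, collection), ds)
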