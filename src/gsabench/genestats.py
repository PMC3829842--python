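"""Gene-level differential expression statistics.

The workhorse is an empirical-Bayes moderated t-statistic: per-gene
residual variances s^2 are shrunk toward a common prior value s0^2,

    s2_post = (d0 * s0^2 + d * s^2) / (d0 + d),

with the prior (s0^2, d0) estimated by moment-matching the scaled-F
marginal distribution of the observed s^2 on the log scale.  Under the
hierarchical model, e = log s^2 - digamma(d/2) + log(d/2) has mean
log s0^2 + digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2)
beyond the sampling variance trigamma(d/2), which yields closed-form
estimates via the inverse trigamma function.  t_mod = effect /
sqrt(s2_post * c) is referred to a t distribution on d0 + d degrees of
freedom (normal when d0 is infinite).

Paired designs are analyzed as a one-sample moderated t on within-block
case-minus-control differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionDataset

log = logging.getLogger(__name__)

__all__ = ["GeneStats", "moderated_t", "bh_fdr", "rank_genes"]


@dataclass
class GeneStats:
    """Per-gene moderated-t results for one dataset."""

    gene_ids: list[str]
    t_mod: np.ndarray
    p: np.ndarray
    lfc: np.ndarray           # log2 fold change, case - control
    s2_post: np.ndarray
    df_resid: float           # d
    df_prior: float           # d0 (may be inf)
    s2_prior: float           # s0^2

    @property
    def rank_by_p(self) -> np.ndarray:
        """1..G ranking by ascending p (ties averaged)."""
        return stats.rankdata(self.p)


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage


def _trigamma_inverse(y):
    """Solve trigamma(x) = y for x > 0 (vectorized Newton iteration)."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F marginal to observed variances.

    Returns ``(s0_sq, d0)``; ``d0`` is ``inf`` when the observed spread of
    log s^2 does not exceed its pure sampling variance.
    Zero variances are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return float(np.mean(s2)) if s2.size else 1.0, np.inf
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        # no excess spread beyond sampling noise: fully pooled prior
        return float(np.mean(s2)), np.inf
    d0 = float(2.0 * _trigamma_inverse(evar)[0])
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return s0_sq, d0


def squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene variances toward the fitted prior.

    Returns ``(s2_post, s0_sq, d0)``.
    """
    s0_sq, d0 = fit_f_dist(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(np.asarray(s2, dtype=float), s0_sq)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return s2_post, s0_sq, d0


def _t_pvalue(t: np.ndarray, df_total: float) -> np.ndarray:
    if np.isinf(df_total):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df_total)


def _moderate(effect, s2, df, c, d0=None, s0_sq=None):
    """Moderated t for one contrast.  When (d0, s0_sq) are given the
    shrinkage limits can be forced (d0=0 ordinary t, d0=inf pooled t)."""
    if d0 is None:
        s2_post, s0_sq, d0 = squeeze_var(s2, df)
    elif d0 == 0:
        s2_post = np.asarray(s2, dtype=float)
        s0_sq = 0.0 if s0_sq is None else s0_sq
    elif np.isinf(d0):
        s2_post = np.full_like(np.asarray(s2, dtype=float), s0_sq)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(s2_post * c)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        log.info("%d gene(s) with zero posterior variance; t set to 0", degenerate.sum())
    t = np.where(degenerate, 0.0, t)
    # total df capped at the pooled residual df (all genes), so d0 = inf
    # yields a t reference rather than a degenerate normal
    df_total = min(d0 + df, np.asarray(s2).size * df)
    p = _t_pvalue(t, df_total)
    p = np.where(degenerate & (np.abs(np.asarray(effect)) > 0), np.finfo(float).tiny, p)
    p = np.where(degenerate & (np.asarray(effect) == 0), 1.0, p)
    return t, p, s2_post, d0, s0_sq


def _unpaired_effect_var(ds: ExpressionDataset):
    case, ctrl = ds.case_idx, ds.control_idx
    n1, n0 = len(case), len(ctrl)
    if n1 < 2 or n0 < 2:
        raise ValueError("unpaired moderated t requires >=2 samples per group")
    x1, x0 = ds.expr[:, case], ds.expr[:, ctrl]
    effect = x1.mean(axis=1) - x0.mean(axis=1)
    ss = x1.var(axis=1, ddof=0) * n1 + x0.var(axis=1, ddof=0) * n0
    df = n1 + n0 - 2
    s2 = ss / df
    c = 1.0 / n1 + 1.0 / n0
    return effect, s2, float(df), c


def _paired_effect_var(ds: ExpressionDataset):
    d = ds.paired_differences()
    nb = d.shape[1]
    if nb < 2:
        raise ValueError("paired moderated t requires >=2 complete blocks")
    effect = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    return effect, s2, float(nb - 1), 1.0 / nb


def moderated_t(ds: ExpressionDataset, *, df_prior: float | None = None,
                s2_prior: float | None = None) -> GeneStats:
    """Moderated t-test, paired or unpaired according to the dataset design.

    ``df_prior``/``s2_prior`` override the empirical-Bayes fit; ``df_prior=0``
    gives the ordinary per-gene t, ``df_prior=inf`` the fully pooled t.
    """
    if ds.is_paired:
        effect, s2, df, c = _paired_effect_var(ds)
    else:
        effect, s2, df, c = _unpaired_effect_var(ds)
    if df_prior is not None and s2_prior is None and np.isinf(df_prior):
        s2_prior = float(np.mean(s2))
    t, p, s2_post, d0, s0_sq = _moderate(effect, s2, df, c, df_prior, s2_prior)
    return GeneStats(
        gene_ids=list(ds.feature_ids),
        t_mod=t, p=p, lfc=effect, s2_post=s2_post,
        df_resid=df, df_prior=float(d0), s2_prior=float(s0_sq),
    )


# ---------------------------------------------------------------------------
# vectorized moderated t across many relabelings (shared by the permutation
# engines; each relabeling gets its own empirical-Bayes fit)


def modt_unpaired_many(expr: np.ndarray, case_indicator: np.ndarray) -> np.ndarray:
    """Moderated t for B group relabelings at once.

    ``case_indicator`` is an (n_samples, B) 0/1 matrix; every column must
    have the same number of cases.  Returns a (G, B) matrix of t statistics.
    """
    Y = np.asarray(case_indicator, dtype=float)
    n = expr.shape[1]
    n1 = int(round(Y[:, 0].sum()))
    n0 = n - n1
    if n1 < 2 or n0 < 2:
        raise ValueError("need >=2 samples per group")
    if not np.allclose(Y.sum(axis=0), n1):
        raise ValueError("relabelings must preserve group sizes")
    df = n - 2
    c = 1.0 / n1 + 1.0 / n0
    X2 = expr ** 2
    sum1 = expr @ Y
    sq1 = X2 @ Y
    sum_all = expr.sum(axis=1, keepdims=True)
    sq_all = X2.sum(axis=1, keepdims=True)
    m1 = sum1 / n1
    m0 = (sum_all - sum1) / n0
    ss = (sq1 - n1 * m1 ** 2) + ((sq_all - sq1) - n0 * m0 ** 2)
    s2 = np.maximum(ss / df, 0.0)
    effect = m1 - m0
    return _modt_many_from_moments(effect, s2, df, c)


def modt_paired_many(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Moderated t for B within-block sign-flip relabelings.

    ``diffs`` is the (G, n_blocks) matrix of case-minus-control differences
    under the observed labelling; ``signs`` is (n_blocks, B) in {-1, +1}.
    """
    nb = diffs.shape[1]
    if nb < 2:
        raise ValueError("need >=2 blocks")
    S = np.asarray(signs, dtype=float)
    effect = diffs @ S / nb
    sq = (diffs ** 2).sum(axis=1, keepdims=True)  # invariant under sign flips
    s2 = np.maximum((sq - nb * effect ** 2) / (nb - 1), 0.0)
    return _modt_many_from_moments(effect, s2, nb - 1, 1.0 / nb)


def _modt_many_from_moments(effect, s2, df, c):
    G, B = s2.shape
    ok = s2 > 0
    n_ok = ok.sum(axis=0)
    z = np.where(ok, np.log(np.where(ok, s2, 1.0)), np.nan)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        emean = np.where(n_ok > 0, np.nanmean(e, axis=0), 0.0)
        evar = np.where(
            n_ok > 1,
            np.nanvar(e, axis=0, ddof=1) - special.polygamma(1, df / 2.0),
            -1.0,
        )
    s2_post = np.empty_like(s2)
    pooled = evar <= 0
    if pooled.any():
        s2_post[:, pooled] = s2[:, pooled].mean(axis=0)[None, :]
    if (~pooled).any():
        d0 = 2.0 * _trigamma_inverse(evar[~pooled])
        s0 = np.exp(emean[~pooled] + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        s2_post[:, ~pooled] = (d0 * s0 + df * s2[:, ~pooled]) / (d0 + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(s2_post * c)
    return np.where(np.isfinite(t), t, 0.0)


# ---------------------------------------------------------------------------


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_genes(gs: GeneStats, key: str = "p") -> np.ndarray:
    """Tie-averaged 1..G ranks: ascending for ``p``, descending for
    ``t``/``abs_t``/``lfc`` (rank 1 = most extreme in the chosen sense)."""
    if key == "p":
        return stats.rankdata(gs.p)
    if key == "t":
        return stats.rankdata(-gs.t_mod)
    if key == "abs_t":
        return stats.rankdata(-np.abs(gs.t_mod))
    if key == "lfc":
        return stats.rankdata(-gs.lfc)
    raise ValueError(f"unknown ranking key {key!r}")
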