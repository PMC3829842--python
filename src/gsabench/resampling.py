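"""Null-generation engines.

Three kinds of resampling are used by the enrichment methods and the
benchmark:

* **sample permutation** — relabel the phenotype within one dataset,
  preserving group sizes; paired designs swap labels within blocks only.
* **gene sampling** — draw random gene sets of a given size from the
  measured universe (competitive nulls).
* **phenotype permutation** — the specificity experiment: every method is
  run on label-permuted versions of each dataset and the fraction of
  set-level p-values below alpha is reported as a false-positive
  percentage.

Whenever the number of distinct relabelings/subsets does not exceed the
requested number of draws, the space is enumerated exhaustively instead of
sampled, which removes Monte-Carlo noise on tiny designs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, GeneSetCollection

log = logging.getLogger(__name__)

__all__ = [
    "PermutationScheme",
    "group_relabelings",
    "permute_samples",
    "sample_random_sets",
    "permutation_pvalue",
    "phenotype_permutation_experiment",
]


@dataclass
class PermutationScheme:
    kind: str = "sample"          # sample | gene | phenotype
    n_perm: int = 1000
    respect_blocks: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"sample", "gene", "phenotype"}:
            raise ValueError(f"unknown permutation kind {self.kind!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


# ---------------------------------------------------------------------------
# sample permutation


def group_relabelings(ds: ExpressionDataset, n_perm: int, rng: np.random.Generator,
                      *, respect_blocks: bool = True) -> tuple[np.ndarray, bool]:
    """Group-label permutations of a dataset.

    Returns ``(labels, exhaustive)`` where ``labels`` is an
    ``(n_samples, B)`` 0/1 matrix of relabelings (identity excluded in
    exhaustive mode) and ``exhaustive`` says whether the space was
    enumerated completely.

    For paired datasets (when ``respect_blocks``) relabelings are
    independent within-block case/control swaps.
    """
    n = ds.n_samples
    if ds.is_paired and respect_blocks:
        blocks = np.unique(ds.block)
        nb = len(blocks)
        n_distinct = 2 ** nb - 1  # excluding identity
        if n_distinct <= n_perm:
            signs = np.array(list(itertools.product([1, -1], repeat=nb))[1:]).T
        else:
            signs = rng.choice([1, -1], size=(nb, n_perm))
        labels = np.repeat(ds.group[:, None], signs.shape[1], axis=1)
        for j, b in enumerate(blocks):
            sel = ds.block == b
            flip = signs[j] == -1
            labels[np.ix_(sel, flip)] = 1 - labels[np.ix_(sel, flip)]
        return labels, n_distinct <= n_perm
    n1 = int(ds.group.sum())
    if n1 < 1 or n - n1 < 1 or (n1 == 1 and n - n1 == 1):
        raise ValueError("design too degenerate to permute")
    n_distinct = comb(n, n1) - 1  # excluding identity
    if n_distinct <= n_perm:
        obs = frozenset(np.flatnonzero(ds.group == 1).tolist())
        cols = [c for c in itertools.combinations(range(n), n1) if frozenset(c) != obs]
        labels = np.zeros((n, len(cols)), dtype=int)
        for j, c in enumerate(cols):
            labels[list(c), j] = 1
        return labels, True
    labels = np.empty((n, n_perm), dtype=int)
    for j in range(n_perm):
        labels[:, j] = rng.permutation(ds.group)
    return labels, False


def permute_samples(ds: ExpressionDataset, scheme: PermutationScheme):
    """Iterate over phenotype-relabeled copies of a dataset."""
    if scheme.kind != "sample":
        raise ValueError("scheme.kind must be 'sample'")
    rng = np.random.default_rng(scheme.seed)
    labels, _ = group_relabelings(
        ds, scheme.n_perm, rng, respect_blocks=scheme.respect_blocks
    )
    paired = ds.is_paired and scheme.respect_blocks
    for j in range(labels.shape[1]):
        yield ds.relabel(labels[:, j], keep_blocks=paired)


def paired_sign_matrix(ds: ExpressionDataset, n_perm: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Within-block sign flips as an (n_blocks, B) matrix in {-1, +1}."""
    nb = len(np.unique(ds.block))
    n_distinct = 2 ** nb - 1
    if n_distinct <= n_perm:
        return np.array(list(itertools.product([1, -1], repeat=nb))[1:]).T, True
    return rng.choice([1, -1], size=(nb, n_perm)), False


# ---------------------------------------------------------------------------
# gene sampling


def sample_random_sets(universe_size: int, m: int, n_perm: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Random same-size gene sets as index arrays, shape (B, m).

    Exhaustive enumeration of all C(universe, m) subsets when that count
    does not exceed ``n_perm``.
    """
    if m > universe_size:
        raise ValueError("set size exceeds universe size")
    total = comb(universe_size, m)
    if total <= n_perm:
        return np.array(list(itertools.combinations(range(universe_size), m))), True
    out = np.empty((n_perm, m), dtype=np.intp)
    for b in range(n_perm):
        out[b] = rng.choice(universe_size, size=m, replace=False)
    return out, False


# ---------------------------------------------------------------------------


def permutation_pvalue(observed: float, nulls, sided: str = "two-sided") -> float:
    """(b + 1) / (B + 1) permutation p-value.

    ``sided`` is ``greater``, ``less`` or ``two-sided`` (absolute values).
    """
    if not np.isfinite(observed):
        raise ValueError("observed statistic is not finite")
    nulls = np.asarray(nulls, dtype=float)
    nulls = nulls[np.isfinite(nulls)]
    if nulls.size == 0:
        raise ValueError("no null statistics")
    if sided == "greater":
        b = np.sum(nulls >= observed)
    elif sided == "less":
        b = np.sum(nulls <= observed)
    elif sided == "two-sided":
        b = np.sum(np.abs(nulls) >= abs(observed))
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return float((b + 1) / (nulls.size + 1))


# ---------------------------------------------------------------------------
# phenotype-permutation specificity experiment


@dataclass
class FalsePositiveTable:
    """Long-format FP table with one row per (method, alpha)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def fp_percent(self, method_id: str, alpha: float) -> float:
        sub = self.table[
            (self.table["method"] == method_id) & (self.table["alpha"] == alpha)
        ]
        if sub.empty:
            raise KeyError(f"no FP entry for {method_id} at alpha={alpha}")
        return float(sub["fp_percent"].iloc[0])


def phenotype_permutation_experiment(
    datasets: list[ExpressionDataset],
    collection: GeneSetCollection,
    method_specs: list,
    n_phen_perm: int = 50,
    alphas: tuple[float, ...] = (0.01, 0.05),
    seed: int = 0,
    runner=None,
) -> FalsePositiveTable:
    """False-positive rates of each method under phenotype permutation.

    Each dataset's group labels are permuted ``n_phen_perm`` times
    (group sizes preserved, identity excluded, pairing ignored under the
    null since labels are exchangeable); every method analyzes every
    permuted dataset and FP%(alpha) = 100 * #(p < alpha) / #tests.

    Per-method failures on individual permuted datasets are logged and
    excluded from that method's totals rather than aborting the run.
    ``runner(spec, ds, collection)`` defaults to
    :func:`gsabench.methods.run_method`.
    """
    if runner is None:
        from .methods import run_method as runner
    rng = np.random.default_rng(seed)
    counts = {spec.method_id: {a: 0 for a in alphas} for spec in method_specs}
    totals = {spec.method_id: 0 for spec in method_specs}
    for ds in datasets:
        for _ in range(n_phen_perm):
            while True:
                labels = rng.permutation(ds.group)
                if not np.array_equal(labels, ds.group):
                    break
            perm_ds = ExpressionDataset(
                expr=ds.expr, feature_ids=ds.feature_ids,
                sample_ids=ds.sample_ids, group=labels, block=None,
                name=f"{ds.name}:perm",
            )
            for spec in method_specs:
                try:
                    res = runner(spec, perm_ds, collection)
                except Exception:  # noqa: BLE001 - fault isolation by design
                    log.warning(
                        "method %s failed on a permuted copy of %s; recorded as NA",
                        spec.method_id, ds.name, exc_info=True,
                    )
                    continue
                p = np.asarray(res["p_value"], dtype=float)
                totals[spec.method_id] += p.size
                for a in alphas:
                    counts[spec.method_id][a] += int(np.sum(p < a))
    rows = []
    for spec in method_specs:
        mid = spec.method_id
        for a in alphas:
            n_tests = totals[mid]
            rows.append(
                {
                    "method": mid,
                    "alpha": a,
                    "n_tests": n_tests,
                    "n_positive": counts[mid][a],
                    "fp_percent": 100.0 * counts[mid][a] / n_tests if n_tests else np.nan,
                }
            )
    return FalsePositiveTable(pd.DataFrame(rows))
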