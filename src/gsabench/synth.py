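"""Synthetic expression data with the structure the benchmark assumes.

The generator emulates RMA-normalized two-group microarray data on the
log2 scale: a Gaussian baseline (mean 8, sd 2), compound-symmetry
correlation within each gene set induced by one latent factor per set,
an optional per-block random intercept for paired designs, and a
designated target set in which a fraction of genes is shifted by a fixed
effect (in units of the per-gene sd), possibly in both directions.

Genes belonging to several sets receive the latent factor of the first
set (in collection order, the target first) that contains them, which
keeps the marginal covariance well defined and preserves the target
set's full internal correlation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .datamodel import ExpressionDataset, GeneSetCollection

__all__ = ["SynthConfig", "SynthTruth", "generate_collection",
           "generate_dataset", "generate_benchmark", "generate_null_suite"]


@dataclass
class SynthConfig:
    """Full description of a simulated benchmark dataset."""

    n_genes: int = 2000
    n_sets: int = 50
    set_size_range: tuple[int, int] = (10, 100)
    target_size: int = 40
    n_per_group: int = 10
    paired: bool = False
    rho: float = 0.1               # within-set compound-symmetry correlation
    de_fraction: float = 0.5       # fraction of target genes shifted
    effect_size: float = 0.8       # shift in units of per-gene sd
    direction_mix: float = 0.0     # fraction of shifted genes down-regulated
    baseline_mean: float = 8.0     # log2-like scale
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid set_size_range")
        if not (lo <= self.target_size <= hi):
            raise ValueError("target_size outside set_size_range")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must be in [0, 1]")
        if not (0.0 <= self.direction_mix <= 1.0):
            raise ValueError("direction_mix must be in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("need >= 2 samples per group")
        if self.target_size > self.n_genes or self.set_size_range[1] > self.n_genes:
            raise ValueError("set sizes exceed the number of genes")


@dataclass
class SynthTruth:
    """Ground truth of one simulated dataset."""

    target_id: str
    shifted: dict[str, float]      # gene id -> signed effect (sd units)
    config: SynthConfig

    def __post_init__(self) -> None:
        pass

    def to_json(self) -> str:
        d = {"target_id": self.target_id, "shifted": self.shifted,
             "config": asdict(self.config)}
        return json.dumps(d, indent=2)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_collection(cfg: SynthConfig,
                        rng: np.random.Generator | None = None,
                        overlap: bool = True) -> tuple[GeneSetCollection, str]:
    """Random gene set collection; the target set (``TARGET``) is drawn
    first.  With ``overlap`` genes are sampled with replacement *across*
    sets (never within), which gives PADOG a non-degenerate gene-frequency
    spectrum; without it sets are pairwise disjoint."""
    rng = rng or np.random.default_rng(cfg.seed)
    genes = np.array(_gene_ids(cfg.n_genes))
    lo, hi = cfg.set_size_range
    sets: dict[str, list[str]] = {}
    target_id = "TARGET"
    sets[target_id] = rng.choice(genes, size=cfg.target_size, replace=False).tolist()
    if not overlap:
        remaining = [g for g in genes if g not in set(sets[target_id])]
        rng.shuffle(remaining)
        pos = 0
    width = len(str(cfg.n_sets))
    for k in range(1, cfg.n_sets):
        size = int(rng.integers(lo, hi + 1))
        sid = f"SET{k:0{width}d}"
        if overlap:
            sets[sid] = rng.choice(genes, size=size, replace=False).tolist()
        else:
            if pos + size > len(remaining):
                raise ValueError("disjoint sets infeasible for these sizes")
            sets[sid] = remaining[pos:pos + size]
            pos += size
    return GeneSetCollection(sets=sets), target_id


def generate_dataset(cfg: SynthConfig, collection: GeneSetCollection,
                     target_id: str,
                     rng: np.random.Generator | None = None,
                     name: str | None = None) -> tuple[ExpressionDataset, SynthTruth]:
    """Simulate one two-group dataset over a collection's gene universe."""
    rng = rng or np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    gidx = {g: i for i, g in enumerate(genes)}
    G = cfg.n_genes
    n = 2 * cfg.n_per_group
    # the first set containing a gene (collection order, target first)
    # owns its latent factor, so the target keeps its full correlation
    factor_of = np.full(G, -1, dtype=int)
    set_ids = collection.set_ids
    for k, sid in enumerate(set_ids):
        for g in collection[sid]:
            i = gidx[g]
            if factor_of[i] < 0:
                factor_of[i] = k
    factors = rng.standard_normal((len(set_ids), n))
    eps = rng.standard_normal((G, n))
    z = np.sqrt(1.0 - cfg.rho) * eps
    shared = factor_of >= 0
    z[shared] += np.sqrt(cfg.rho) * factors[factor_of[shared]]
    expr = cfg.baseline_mean + cfg.baseline_sd * z

    group = np.array([1] * cfg.n_per_group + [0] * cfg.n_per_group)
    block = None
    sample_ids = [f"S{j:02d}" for j in range(n)]
    if cfg.paired:
        block = np.array(list(range(cfg.n_per_group)) * 2)
        intercepts = rng.normal(0.0, cfg.baseline_sd / 2.0, size=cfg.n_per_group)
        expr += intercepts[block][None, :]

    target_genes = collection[target_id]
    k = int(round(cfg.de_fraction * len(target_genes)))
    chosen = rng.choice(len(target_genes), size=k, replace=False)
    n_down = int(round(cfg.direction_mix * k))
    signs = np.ones(k)
    if n_down:
        signs[rng.choice(k, size=n_down, replace=False)] = -1.0
    shifted: dict[str, float] = {}
    for j, s in zip(chosen, signs):
        gene = target_genes[j]
        delta = float(s * cfg.effect_size)
        shifted[gene] = delta
        expr[gidx[gene], group == 1] += delta * cfg.baseline_sd
    ds = ExpressionDataset(
        expr=expr, feature_ids=genes, sample_ids=sample_ids,
        group=group, block=block, name=name or f"synth-seed{cfg.seed}",
    )
    return ds, SynthTruth(target_id, shifted, cfg)


def generate_benchmark(cfg: SynthConfig, n_datasets: int,
                       ) -> tuple[GeneSetCollection, str, list[tuple[ExpressionDataset, SynthTruth]]]:
    """One collection plus ``n_datasets`` replicate datasets with child
    seeds derived from the master seed."""
    ss = np.random.SeedSequence(cfg.seed)
    child = ss.spawn(n_datasets + 1)
    collection, target_id = generate_collection(cfg, np.random.default_rng(child[0]))
    out = []
    for i in range(n_datasets):
        ds, truth = generate_dataset(
            cfg, collection, target_id, np.random.default_rng(child[i + 1]),
            name=f"synth{i:03d}",
        )
        out.append((ds, truth))
    return collection, target_id, out


def generate_null_suite(cfg: SynthConfig, n_datasets: int,
                        ) -> tuple[GeneSetCollection, str, list[ExpressionDataset]]:
    """Replicate datasets with the effect forced to zero (correlations and
    design retained) — the no-differential-expression regime."""
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    null_cfg = SynthConfig(**{**asdict(cfg), "effect_size": 0.0, "de_fraction": 0.0})
    null_cfg.set_size_range = tuple(null_cfg.set_size_range)
    collection, target_id, pairs = generate_benchmark(null_cfg, n_datasets)
    for _, truth in pairs:
        assert not truth.shifted
    return collection, target_id, [ds for ds, _ in pairs]
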