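"""Over-representation analysis (ORA).

A one-tailed hypergeometric test of the overlap between a list of
differentially expressed (DE) genes and each gene set.  DE genes are
selected by a three-step cascade designed to always yield a usable list:

1. all genes with BH-FDR adjusted p < 0.1, if more than 200 genes pass;
2. otherwise all genes with nominal p < 0.05 and fold change > 1.5
   (|log2 fc| > log2 1.5), if more than 200 pass;
3. otherwise the top 1% of genes by nominal p (at least 1 gene).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from ..datamodel import ExpressionDataset, GeneSetCollection, MethodResult
from ..genestats import GeneStats, bh_fdr
from ._engine import DatasetStats

FC_THRESHOLD = math.log2(1.5)


def ora_select_de(gs: GeneStats) -> list[str]:
    """DE gene list via the FDR / p+fold-change / top-1% cascade."""
    genes = np.asarray(gs.gene_ids)
    adj = bh_fdr(gs.p)
    rule1 = adj < 0.1
    if rule1.sum() > 200:
        return genes[rule1].tolist()
    rule2 = (gs.p < 0.05) & (np.abs(gs.lfc) > FC_THRESHOLD)
    if rule2.sum() > 200:
        return genes[rule2].tolist()
    k = max(1, math.ceil(len(genes) / 100))
    order = np.lexsort((genes, gs.p))  # ties by smaller p then gene id
    return genes[order[:k]].tolist()


def ora_test(de: list[str], universe: list[str], set_genes: list[str],
             method_id: str = "ORA") -> MethodResult:
    """One-tailed hypergeometric p = P(X >= k) for the DE/set overlap."""
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    de_set = set(de) & uni
    members = [g for g in set_genes if g in uni]
    if not members:
        raise ValueError("set has no genes in the universe")
    k = len(de_set & set(members))
    N, K, n = len(uni), len(de_set), len(members)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return MethodResult(set_id="", size_used=n, statistic=float(k),
                        p_value=min(p, 1.0), method_id=method_id)


def run_ora(ds: ExpressionDataset, collection: GeneSetCollection,
            spec, cache: DatasetStats) -> list[MethodResult]:
    gs = cache.gene_stats()
    de = ora_select_de(gs)
    out = []
    for sid, genes in collection.sets.items():
        r = ora_test(de, ds.feature_ids, genes)
        r.set_id = sid
        out.append(r)
    return out
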