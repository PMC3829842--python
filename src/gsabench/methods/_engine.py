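"""Shared per-dataset computation cache for the enrichment methods.

All sample-permutation methods (GSEA, GSA, SAFE, PADOG, SIGPATHWAY-Q2)
consume the same null object: a (genes x permutations) matrix of moderated
t statistics recomputed under phenotype relabelings (within-block swaps
for paired designs).  Computing that matrix once per dataset and sharing
it across methods keeps a 16-method benchmark run tractable; with a fixed
seed the permutation stream is identical no matter which methods request
it, so results are reproducible method by method.
"""

from __future__ import annotations

import numpy as np

from ..datamodel import ExpressionDataset
from ..genestats import GeneStats, moderated_t, modt_paired_many, modt_unpaired_many
from ..resampling import group_relabelings, paired_sign_matrix


class DatasetStats:
    """Lazy cache of gene-level statistics for one dataset."""

    def __init__(self, ds: ExpressionDataset):
        self.ds = ds
        self._gene_stats: GeneStats | None = None
        self._perm_t: dict[tuple[int, int], tuple[np.ndarray, bool]] = {}

    def gene_stats(self) -> GeneStats:
        if self._gene_stats is None:
            self._gene_stats = moderated_t(self.ds)
        return self._gene_stats

    def perm_t(self, n_perm: int, seed: int) -> tuple[np.ndarray, bool]:
        """(G, B) matrix of moderated t under B relabelings, and whether
        the relabeling space was enumerated exhaustively (identity
        excluded)."""
        key = (n_perm, seed)
        if key not in self._perm_t:
            rng = np.random.default_rng(seed)
            ds = self.ds
            if ds.is_paired:
                signs, exhaustive = paired_sign_matrix(ds, n_perm, rng)
                T = modt_paired_many(ds.paired_differences(), signs)
            else:
                labels, exhaustive = group_relabelings(ds, n_perm, rng)
                T = modt_unpaired_many(ds.expr, labels)
            self._perm_t[key] = (T, exhaustive)
        return self._perm_t[key]
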