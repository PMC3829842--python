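"""Core domain types.

The unit of analysis is a two-group (optionally paired) log2 expression
matrix together with a collection of named gene sets.  Every enrichment
method consumes these two objects and emits one :class:`MethodResult` per
gene set, assembled into a result table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "TargetAnnotation",
    "MethodResult",
    "make_result_table",
    "RESULT_COLUMNS",
]


@dataclass
class ExpressionDataset:
    """A genes x samples log2 expression matrix with a binary phenotype.

    Parameters
    ----------
    expr
        Array of shape ``(n_features, n_samples)`` holding log2 intensities.
    feature_ids
        Row identifiers (probesets or gene ids).
    sample_ids
        Column identifiers.
    group
        Per-sample binary label, 1 = case, 0 = control.
    block
        Optional per-sample pairing identifier.  When given, every block
        must contain exactly one case and one control.
    name
        Free-form dataset label.
    """

    expr: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    group: np.ndarray
    block: np.ndarray | None = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.group = np.asarray(self.group, dtype=int)
        if self.expr.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        g, n = self.expr.shape
        if len(self.feature_ids) != g:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {g} expression rows"
            )
        if len(self.sample_ids) != n or len(self.group) != n:
            raise ValueError("sample ids / group labels do not match columns")
        if len(set(self.feature_ids)) != g:
            raise ValueError("feature ids must be unique")
        if not np.isfinite(self.expr).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        levels = set(self.group.tolist())
        if not levels <= {0, 1} or len(levels) != 2:
            raise ValueError("group must contain both labels 0 and 1")
        if self.block is not None:
            self.block = np.asarray(self.block)
            if len(self.block) != n:
                raise ValueError("block length does not match samples")
            for b in np.unique(self.block):
                sub = self.group[self.block == b]
                if len(sub) != 2 or sub.sum() != 1:
                    raise ValueError(
                        f"block {b!r} must contain exactly one case and one control"
                    )

    # -- convenience -------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    @property
    def is_paired(self) -> bool:
        return self.block is not None

    @property
    def case_idx(self) -> np.ndarray:
        return np.flatnonzero(self.group == 1)

    @property
    def control_idx(self) -> np.ndarray:
        return np.flatnonzero(self.group == 0)

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def relabel(self, group: np.ndarray, *, keep_blocks: bool = False) -> "ExpressionDataset":
        """Copy of the dataset with a new phenotype labelling.

        Permuted phenotypes break the case/control pairing, so blocks are
        dropped unless the relabelling is a within-block swap
        (``keep_blocks=True``).
        """
        return dataclasses.replace(
            self, group=np.asarray(group, dtype=int),
            block=self.block if keep_blocks else None,
        )

    def paired_differences(self) -> np.ndarray:
        """Per-block case-minus-control differences, shape (G, n_blocks)."""
        if self.block is None:
            raise ValueError("dataset is not paired")
        blocks = np.unique(self.block)
        out = np.empty((self.n_features, len(blocks)))
        for j, b in enumerate(blocks):
            sel = self.block == b
            case = self.expr[:, sel & (self.group == 1)][:, 0]
            ctrl = self.expr[:, sel & (self.group == 0)][:, 0]
            out[:, j] = case - ctrl
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets; order of genes within a set is preserved."""

    sets: dict[str, list[str]]
    display_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {sid!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {sid!r} has duplicate gene ids")
        for sid in self.sets:
            self.display_names.setdefault(sid, sid)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __getitem__(self, set_id: str) -> list[str]:
        return self.sets[set_id]

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {sid: len(g) for sid, g in self.sets.items()}

    def indicator(self, feature_ids: list[str]) -> np.ndarray:
        """Boolean membership matrix of shape (n_sets, n_features)."""
        idx = {f: i for i, f in enumerate(feature_ids)}
        out = np.zeros((len(self.sets), len(feature_ids)), dtype=bool)
        for r, genes in enumerate(self.sets.values()):
            for gene in genes:
                j = idx.get(gene)
                if j is not None:
                    out[r, j] = True
        return out

    def gene_frequencies(self) -> dict[str, int]:
        """Number of sets each gene belongs to (PADOG weighting input)."""
        freq: dict[str, int] = {}
        for genes in self.sets.values():
            for gene in genes:
                freq[gene] = freq.get(gene, 0) + 1
        return freq


@dataclass
class TargetAnnotation:
    """Mapping dataset name -> id of the disease ("target") gene set."""

    targets: dict[str, str]

    def validate(self, collection: GeneSetCollection) -> None:
        missing = [s for s in self.targets.values() if s not in collection]
        if missing:
            raise ValueError(f"target set ids not in collection: {missing}")

    def __getitem__(self, dataset_name: str) -> str:
        return self.targets[dataset_name]


@dataclass
class MethodResult:
    """One gene set's score under one method."""

    set_id: str
    size_used: int
    statistic: float
    p_value: float
    method_id: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.size_used < 1:
            raise ValueError("size_used must be >= 1")


RESULT_COLUMNS = ["set_id", "size_used", "statistic", "p_value", "rank_pct"]


def make_result_table(results: list[MethodResult]) -> pd.DataFrame:
    """Assemble per-set results, sorted by ascending p, with rank percentages.

    ``rank_pct`` is the tie-averaged rank of each set's p-value expressed as
    a percentage of the number of sets analyzed.
    """
    from scipy.stats import rankdata

    if not results:
        raise ValueError("no results to tabulate")
    df = pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "size_used": [r.size_used for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
    df["rank_pct"] = 100.0 * rankdata(df["p_value"]) / len(df)
    df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    df.attrs["method_id"] = results[0].method_id
    return df
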