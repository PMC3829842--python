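"""Method registry and the uniform ``run_method`` entry point."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..datamodel import ExpressionDataset, GeneSetCollection, MethodResult, make_result_table
from . import fcs, gsea, ora, singlesample
from ._engine import DatasetStats
from ._util import set_indices

METHOD_IDS = [
    "ORA", "MRGSE", "SAFE", "SIGPATHWAY_Q1", "SIGPATHWAY_Q2", "GSA",
    "PADOG", "GAGE", "CAMERA", "GLOBALTEST", "GSEA", "GSEAP",
    "PLAGE", "ZSCORE", "SSGSEA", "GSVA",
]

#: gene- vs subject-sampling character of each statistic's null
SAMPLING_TYPE = {
    "ORA": "gene", "MRGSE": "gene", "GSEAP": "gene", "GAGE": "gene",
    "SIGPATHWAY_Q1": "gene",
    "SAFE": "subject", "SIGPATHWAY_Q2": "subject", "GSA": "subject",
    "PADOG": "subject", "CAMERA": "subject", "GLOBALTEST": "subject",
    "GSEA": "subject", "PLAGE": "subject", "ZSCORE": "subject",
    "SSGSEA": "subject", "GSVA": "subject",
}


@dataclass
class MethodSpec:
    """Which statistic to run and how its null is drawn."""

    method_id: str
    n_perm: int = 1000
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method_id not in METHOD_IDS:
            raise ValueError(
                f"unknown method {self.method_id!r}; valid: {', '.join(METHOD_IDS)}"
            )
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @property
    def sampling_type(self) -> str:
        return SAMPLING_TYPE[self.method_id]


def _per_set(fun, ds, collection, *args, **kwargs) -> list[MethodResult]:
    out = []
    for sid, genes in collection.sets.items():
        r = fun(ds, genes, *args, **kwargs)
        r.set_id = sid
        out.append(r)
    return out


def _run_gsea_collection(ds, collection, spec, cache) -> list[MethodResult]:
    """GSEA over a whole collection, sharing the per-permutation ranking."""
    t = cache.gene_stats().t_mod
    idx_list = [set_indices(ds.feature_ids, g) for g in collection.sets.values()]
    if np.all(t == 0):
        return [MethodResult(sid, len(ix), 0.0, 1.0, "GSEA")
                for sid, ix in zip(collection.set_ids, idx_list)]
    T, _ = cache.perm_t(spec.n_perm, spec.seed)
    obs = gsea._es_for_sets(t, idx_list, 1.0)
    nulls = np.empty((len(idx_list), T.shape[1]))
    for b in range(T.shape[1]):
        col = T[:, b]
        if np.all(col == 0):
            nulls[:, b] = 0.0
        else:
            nulls[:, b] = gsea._es_for_sets(col, idx_list, 1.0)
    return [
        MethodResult(sid, len(ix), float(obs[i]),
                     gsea._signed_pool_p(obs[i], nulls[i]), "GSEA")
        for i, (sid, ix) in enumerate(zip(collection.set_ids, idx_list))
    ]


def run_method(spec: MethodSpec, ds: ExpressionDataset,
               collection: GeneSetCollection,
               cache: DatasetStats | None = None) -> pd.DataFrame:
    """Run one method on one dataset over a gene set collection.

    Returns a result table (one row per set, sorted by ascending p, with
    tie-averaged rank percentages).  ``cache`` lets callers share gene-level
    and permutation statistics across methods on the same dataset.
    """
    cache = cache or DatasetStats(ds)
    mid = spec.method_id
    if mid == "ORA":
        results = ora.run_ora(ds, collection, spec, cache)
    elif mid == "MRGSE":
        results = []
        gs = cache.gene_stats()
        for sid, genes in collection.sets.items():
            r = fcs.mean_rank_test(gs, genes)
            r.set_id = sid
            results.append(r)
    elif mid == "SAFE":
        results = _per_set(fcs.safe_test, ds, collection, spec, cache)
    elif mid in ("SIGPATHWAY_Q1", "SIGPATHWAY_Q2"):
        hyp = mid.split("_")[1]
        results = _per_set(fcs.sigpathway_test, ds, collection, spec, hyp, cache)
    elif mid == "GSA":
        results = _per_set(fcs.gsa_maxmean_test, ds, collection, spec, cache)
    elif mid == "PADOG":
        results = fcs.run_padog(ds, collection, spec, cache)
    elif mid == "GAGE":
        results = _per_set(fcs.gage_test, ds, collection, spec, cache)
    elif mid == "CAMERA":
        results = _per_set(fcs.camera_test, ds, collection, spec, cache)
    elif mid == "GLOBALTEST":
        results = _per_set(
            fcs.globaltest_test, ds, collection, spec, cache,
            pvalue=spec.params.get("pvalue", "moment"),
        )
    elif mid == "GSEA":
        results = _run_gsea_collection(ds, collection, spec, cache)
    elif mid == "GSEAP":
        results = _per_set(gsea.gseap_test, ds, collection, spec, cache)
    elif mid in ("PLAGE", "ZSCORE", "SSGSEA", "GSVA"):
        results = singlesample.run_single_sample(mid, ds, collection)
    else:  # pragma: no cover
        raise AssertionError(mid)
    return make_result_table(results)
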