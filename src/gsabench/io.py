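"""Readers/writers for GMT and TSV formats and matrix preprocessing.

Preprocessing mirrors standard microarray practice: multiple probesets per
gene are collapsed to the probeset with the highest average expression, and
gene set collections are restricted to the measured genes before any
method runs so that every method sees identical set definitions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, GeneSetCollection

log = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "collapse_features",
    "restrict_collection",
]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``set_id<TAB>description<TAB>genes...``.

    Duplicate gene ids within a line are dropped (order preserved, warning
    logged); a duplicated set id is an error.
    """
    sets: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            sid, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}: line {lineno}: set {sid!r} has no genes")
            if sid in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set id {sid!r}")
            seen: set[str] = set()
            unique = []
            for g in genes:
                if g in seen:
                    continue
                seen.add(g)
                unique.append(g)
            if len(unique) != len(genes):
                log.warning(
                    "%s: line %d: dropped %d duplicate gene id(s) in set %s",
                    path, lineno, len(genes) - len(unique), sid,
                )
            sets[sid] = unique
            names[sid] = desc
    return GeneSetCollection(sets=sets, display_names=names)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, genes in collection.sets.items():
            desc = collection.display_names.get(sid, sid)
            fh.write("\t".join([sid, desc, *genes]) + "\n")


def read_expression(expr_path, meta_path, name: str | None = None) -> ExpressionDataset:
    """Load an expression TSV (features x samples) plus a sample metadata TSV.

    The metadata table must have columns ``sample`` and ``group`` and may
    have a ``block`` column; expression columns are reordered to the
    metadata order.  Group labels are coerced to {0, 1}: if already 0/1
    they are kept, otherwise the lexicographically larger of the two
    labels becomes the case (1).
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "sample" not in meta.columns or "group" not in meta.columns:
        raise ValueError("metadata must have 'sample' and 'group' columns")
    expr.columns = expr.columns.astype(str)
    samples = meta["sample"].tolist()
    missing = set(samples) - set(expr.columns)
    extra = set(expr.columns) - set(samples)
    if missing or extra:
        raise ValueError(
            f"sample mismatch between files: missing {sorted(missing)}, "
            f"unmatched {sorted(extra)}"
        )
    expr = expr[samples]
    values = expr.to_numpy(dtype=float)  # raises on non-numeric cells
    levels = sorted(set(meta["group"]))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {levels}")
    if set(levels) == {"0", "1"}:
        group = meta["group"].astype(int).to_numpy()
    else:
        group = (meta["group"] == levels[1]).astype(int).to_numpy()
    block = None
    if "block" in meta.columns and meta["block"].notna().all():
        block = meta["block"].to_numpy()
    return ExpressionDataset(
        expr=values,
        feature_ids=expr.index.astype(str).tolist(),
        sample_ids=samples,
        group=group,
        block=block,
        name=name or str(expr_path),
    )


def write_expression(ds: ExpressionDataset, expr_path, meta_path) -> None:
    pd.DataFrame(ds.expr, index=ds.feature_ids, columns=ds.sample_ids).to_csv(
        expr_path, sep="\t", index_label="feature"
    )
    meta = pd.DataFrame({"sample": ds.sample_ids, "group": ds.group})
    if ds.block is not None:
        meta["block"] = ds.block
    meta.to_csv(meta_path, sep="\t", index=False)


def collapse_features(
    ds: ExpressionDataset, feature_to_gene: dict[str, str]
) -> ExpressionDataset:
    """Collapse probesets to genes, keeping the probeset with the highest
    average expression across all samples; ties go to the lexicographically
    smallest feature id.  Features without a mapping are dropped.
    """
    if not feature_to_gene:
        raise ValueError("empty feature-to-gene mapping")
    means = ds.expr.mean(axis=1)
    best: dict[str, tuple[float, str, int]] = {}
    for i, feat in enumerate(ds.feature_ids):
        gene = feature_to_gene.get(feat)
        if gene is None:
            continue
        cand = (-means[i], feat, i)  # min over (-mean, feature_id) = max mean, tie -> smaller id
        prev = best.get(gene)
        if prev is None:
            best[gene] = cand
        elif cand < prev:
            if cand[0] == prev[0]:
                log.info("gene %s: mean-expression tie, keeping probeset %s", gene, feat)
            best[gene] = cand
        elif cand[0] == prev[0]:
            log.info("gene %s: mean-expression tie, keeping probeset %s", gene, prev[1])
    if not best:
        raise ValueError("no features mapped to genes")
    genes = sorted(best)
    rows = [best[g][2] for g in genes]
    return ExpressionDataset(
        expr=ds.expr[rows, :],
        feature_ids=genes,
        sample_ids=ds.sample_ids,
        group=ds.group,
        block=ds.block,
        name=ds.name,
    )


def restrict_collection(
    collection: GeneSetCollection,
    ds: ExpressionDataset,
    min_size: int = 3,
    max_size: int | None = None,
) -> GeneSetCollection:
    """Intersect every set with the measured genes and drop sets whose
    restricted size falls outside ``[min_size, max_size]``.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    measured = set(ds.feature_ids)
    sets: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    for sid, genes in collection.sets.items():
        kept = [g for g in genes if g in measured]
        if len(kept) < min_size:
            continue
        if max_size is not None and len(kept) > max_size:
            continue
        sets[sid] = kept
        names[sid] = collection.display_names.get(sid, sid)
    if not sets:
        raise ValueError("no gene sets remain after restriction")
    return GeneSetCollection(sets=sets, display_names=names)
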