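"""Benchmarking framework: sensitivity, prioritization, specificity.

For every (dataset, method) pair the benchmark records the p-value and
rank percentage of that dataset's *target* gene set — the disease set
expected to be relevant.  Per-method summaries (median target p as the
sensitivity surrogate, median rank % as the prioritization score, and the
phenotype-permutation false-positive percentage as specificity) are
combined into robust Z-scores,

    z = (x - median(x)) / (1.4826 * MAD(x)),

computed across the methods of a category, and methods are ranked by the
sum of their Z-scores (smaller = better).  Methods whose false-positive
rate under phenotype permutation is far above nominal form category II
and their specificity Z-score joins the sum; the well-calibrated methods
form category I.  Ranking stability is assessed by splitting the datasets
on sample size, target set size, design and effect size and correlating
each subset ranking with the overall one (Spearman).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "target_rank_pct", "collect_records", "method_metrics",
    "overall_relevance_test", "robust_z", "categorize", "rank_methods",
    "scenario_rankings", "ScenarioReport",
]

MAD_SCALE = 1.4826  # normal-consistency factor


def target_rank_pct(results: pd.DataFrame, target_id: str) -> float:
    """Tie-averaged rank of the target set's p-value as a percentage of the
    number of sets analyzed (0-100]."""
    if target_id not in set(results["set_id"]):
        raise KeyError(f"target set {target_id!r} absent from results")
    ranks = stats.rankdata(results["p_value"])
    pos = results.index[results["set_id"] == target_id][0]
    loc = results.index.get_loc(pos)
    return float(100.0 * ranks[loc] / len(results))


def collect_records(results_by_dataset: dict[str, dict[str, pd.DataFrame]],
                    targets: dict[str, str]) -> pd.DataFrame:
    """Benchmark records: one row per (dataset, method) with the target
    set's p-value and rank percentage.

    ``results_by_dataset`` maps dataset name -> method_id -> result table.
    """
    rows = []
    for ds_name, per_method in results_by_dataset.items():
        tid = targets[ds_name]
        for mid, table in per_method.items():
            tp = float(table.loc[table["set_id"] == tid, "p_value"].iloc[0])
            rows.append({
                "dataset": ds_name, "method_id": mid,
                "target_p": tp, "target_rank_pct": target_rank_pct(table, tid),
            })
    return pd.DataFrame(rows)


def method_metrics(records: pd.DataFrame, fp_table=None,
                   alphas: tuple[float, ...] = (0.01, 0.05)) -> pd.DataFrame:
    """Per-method medians of target p and rank %, classical sensitivity at
    each alpha, and (when an FP table from the phenotype-permutation
    experiment is given) false-positive percentages."""
    if records.empty:
        raise ValueError("no benchmark records")
    rows = []
    for mid, sub in records.groupby("method_id", sort=False):
        row = {
            "method_id": mid,
            "med_p": float(sub["target_p"].median()),
            "med_rank": float(sub["target_rank_pct"].median()),
            "n_datasets": len(sub),
        }
        for a in alphas:
            row[f"sens_at_{a}"] = float((sub["target_p"] < a).mean())
        if fp_table is not None:
            for a in alphas:
                try:
                    row[f"fp_pct_{a}"] = fp_table.fp_percent(mid, a)
                except KeyError:
                    row[f"fp_pct_{a}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("method_id")


def overall_relevance_test(records: pd.DataFrame) -> pd.DataFrame:
    """One-sided Wilcoxon signed-rank per method: are target p-values
    centered below 0.5, and target rank percentages below 50%?"""
    rows = []
    for mid, sub in records.groupby("method_id", sort=False):
        if len(sub) < 6:
            raise ValueError("need >= 6 datasets for the signed-rank test")
        rows.append({
            "method_id": mid,
            "wilcoxon_p_vs_half": _signed_rank_less(sub["target_p"].to_numpy(), 0.5),
            "wilcoxon_rank_vs_50": _signed_rank_less(
                sub["target_rank_pct"].to_numpy(), 50.0),
        })
    return pd.DataFrame(rows).set_index("method_id")


def _signed_rank_less(x: np.ndarray, center: float) -> float:
    d = x - center
    if np.all(d == 0):
        return 1.0
    return float(stats.wilcoxon(d, alternative="less").pvalue)


def robust_z(values) -> np.ndarray:
    """(x - median) / (1.4826 * MAD); requires >= 3 values and MAD > 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("robust Z needs >= 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError("MAD is zero; robust Z undefined")
    return (x - med) / (MAD_SCALE * mad)


def categorize(fp_pct_at_1pct: float, threshold_pct: float = 3.0) -> str:
    """Category II = false-positive percentage at alpha=1% far above
    nominal; the 3% default separates well-calibrated methods (observed
    FP up to ~2.5%) from the inflated gene-sampling group (>= ~5%)."""
    return "II" if fp_pct_at_1pct > threshold_pct else "I"


def rank_methods(metrics: pd.DataFrame, categories: dict[str, str] | None = None,
                 fp_column: str = "fp_pct_0.01") -> pd.DataFrame:
    """Robust-Z ranking table (one row per method).

    Category I methods sum the sensitivity (median p) and prioritization
    (median rank) Z-scores; category II methods additionally include the
    specificity (FP%) Z-score.  Z-scores are computed within category.
    Rank 1 = smallest sum; ties broken by lower median rank then method id.
    """
    if categories is None:
        if fp_column not in metrics.columns:
            raise ValueError("no categories given and no FP column to derive them")
        categories = {m: categorize(metrics.loc[m, fp_column]) for m in metrics.index}
    out = metrics.copy()
    out["category"] = [categories[m] for m in out.index]
    out["z_sens"] = np.nan
    out["z_prior"] = np.nan
    out["z_spec"] = np.nan
    out["z_sum"] = np.nan
    for cat, sub in out.groupby("category"):
        if len(sub) < 3:
            raise ValueError(f"category {cat} has fewer than 3 methods")
        z_sens = robust_z(sub["med_p"])
        z_prior = robust_z(sub["med_rank"])
        out.loc[sub.index, "z_sens"] = z_sens
        out.loc[sub.index, "z_prior"] = z_prior
        z_sum = z_sens + z_prior
        if cat == "II":
            fp = sub[fp_column] if fp_column in sub.columns else pd.Series(
                np.nan, index=sub.index)
            if np.isfinite(fp.to_numpy(dtype=float)).all():
                z_spec = robust_z(fp)
                out.loc[sub.index, "z_spec"] = z_spec
                z_sum = z_sum + z_spec
            # else: z_spec stays NA and the sum falls back to the two
            # available criteria
        out.loc[sub.index, "z_sum"] = z_sum
    ranks = pd.Series(index=out.index, dtype=float)
    for cat, sub in out.groupby("category"):
        order = (sub.assign(_mid=sub.index.astype(str))
                 .sort_values(["z_sum", "med_rank", "_mid"], kind="mergesort")
                 .index)
        ranks.loc[order] = np.arange(1, len(order) + 1)
    out["rank_in_category"] = ranks.astype(int)
    return out


@dataclass
class ScenarioReport:
    """Ranking stability report for one stratification factor."""

    factor: str
    cutoff: float | str
    subset_tables: dict[str, pd.DataFrame]
    spearman_vs_overall: dict[str, dict[str, float]]  # subset -> category -> rho
    low_n: dict[str, bool]


_FACTORS = {
    "sample_size": "n_samples",
    "set_size": "target_set_size",
    "design": "paired",
    "effect": "pct_de_genes",
}


def scenario_rankings(records: pd.DataFrame, dataset_features: pd.DataFrame,
                      categories: dict[str, str],
                      fp_table=None) -> list[ScenarioReport]:
    """Scenario-stratified rankings and their Spearman agreement with the
    overall ranking.

    ``dataset_features`` is indexed by dataset name with columns
    ``n_samples``, ``target_set_size``, ``paired`` (bool) and
    ``pct_de_genes`` (% of genes with nominal p < 0.05).  Numeric factors
    split at their median; the FP/specificity Z never enters subset sums
    for category I, and for category II the overall FP values are reused
    (specificity does not depend on the dataset split).
    """
    overall = rank_methods(_with_fp(method_metrics(records, fp_table), fp_table),
                           categories)
    reports = []
    for factor, col in _FACTORS.items():
        feat = dataset_features[col]
        if factor == "design":
            cutoff = "paired"
            groups = {"paired": feat[feat.astype(bool)].index,
                      "unpaired": feat[~feat.astype(bool)].index}
        else:
            cutoff = float(feat.median())
            groups = {"small": feat[feat < cutoff].index,
                      "large": feat[feat >= cutoff].index}
        subset_tables, spearman, low_n = {}, {}, {}
        for gname, ds_names in groups.items():
            sub = records[records["dataset"].isin(ds_names)]
            if sub.empty:
                continue
            tbl = rank_methods(_with_fp(method_metrics(sub, fp_table), fp_table),
                               categories)
            subset_tables[gname] = tbl
            low_n[gname] = len(set(sub["dataset"])) < 3
            spearman[gname] = {}
            for cat in sorted(set(categories.values())):
                mids = [m for m in overall.index if categories[m] == cat]
                rho = stats.spearmanr(
                    overall.loc[mids, "rank_in_category"],
                    tbl.loc[mids, "rank_in_category"],
                ).statistic
                spearman[gname][cat] = float(rho)
        reports.append(ScenarioReport(factor, cutoff, subset_tables,
                                      spearman, low_n))
    return reports


def _with_fp(metrics: pd.DataFrame, fp_table) -> pd.DataFrame:
    if fp_table is None and "fp_pct_0.01" not in metrics.columns:
        metrics = metrics.copy()
        metrics["fp_pct_0.01"] = np.nan
    return metrics
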