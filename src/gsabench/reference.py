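"""Published 42-dataset benchmark summary used to validate the ranking
machinery.

A large microarray compendium evaluation of these sixteen methods (42
GEO disease datasets, KEGG and Metacore disease gene sets) reported, per
method, the median target-set p-value (sensitivity surrogate), the median
target-set rank percentage (prioritization), and the false-positive
percentage at alpha = 1% under phenotype permutation (specificity),
together with the derived robust Z-scores and category ranks.  The raw
columns are bundled here so the Z-score combination, categorization and
scenario-stability code can be checked against known outputs without
access to the underlying microarray data.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_method_summary", "published_scenario_ranks"]

# method, sampling type, category, med. p, med. rank (%), FP% at alpha=1%
_SUMMARY_ROWS = [
    ("PLAGE",         "subject", "I",  0.0022, 25.0, 1.1),
    ("GLOBALTEST",    "subject", "I",  0.0001, 27.9, 2.0),
    ("PADOG",         "subject", "I",  0.0960,  9.7, 2.5),
    ("ORA",           "gene",    "I",  0.0732, 18.3, 2.5),
    ("SAFE",          "subject", "I",  0.1065, 18.8, 1.3),
    ("SIGPATHWAY_Q2", "subject", "I",  0.0565, 38.0, 0.9),
    ("GSA",           "subject", "I",  0.1420, 21.0, 1.3),
    ("SSGSEA",        "subject", "I",  0.0808, 40.3, 1.0),
    ("ZSCORE",        "subject", "I",  0.0950, 39.8, 1.0),
    ("GSEA",          "subject", "I",  0.1801, 33.1, 2.3),
    ("GSVA",          "subject", "I",  0.1986, 51.5, 1.1),
    ("CAMERA",        "subject", "I",  0.3126, 43.0, 0.5),
    ("MRGSE",         "gene",    "II", 0.0100, 18.8, 4.9),
    ("GSEAP",         "gene",    "II", 0.0644, 36.2, 15.8),
    ("GAGE",          "gene",    "II", 0.0024, 35.9, 37.9),
    ("SIGPATHWAY_Q1", "gene",    "II", 0.1165, 49.7, 17.2),
]

# per-category ranks under eight dataset splits (the compendium's
# scenario-stability analysis): overall, sample size below/above the
# median of 22, target set size below/above the median of 66, paired vs
# unpaired design, effect size (% genes with p < 0.05) below/above 24.6%
_SCENARIO_ROWS = [
    ("PLAGE",         "I",  1,  1,  4,  2,  3, 12,  2,  3,  3),
    ("GLOBALTEST",    "I",  2,  2,  1,  3,  5,  6,  1,  2,  4),
    ("PADOG",         "I",  3,  3,  2,  1,  2,  1,  3,  1,  1),
    ("ORA",           "I",  4,  4,  3,  5,  1,  2,  4,  5,  2),
    ("SAFE",          "I",  5,  7,  5,  4,  8,  8,  5,  4,  6),
    ("SIGPATHWAY_Q2", "I",  6,  5,  8,  8,  4,  5,  7,  8,  8),
    ("GSA",           "I",  7,  9,  6,  7,  6, 11,  6,  6, 11),
    ("SSGSEA",        "I",  8,  8,  7,  6, 12,  4,  8,  9,  5),
    ("ZSCORE",        "I",  9,  6, 10, 10,  7,  9, 10,  7,  9),
    ("GSEA",          "I", 10, 10,  9,  9, 11, 10,  9, 10,  7),
    ("GSVA",          "I", 11, 11, 11, 11,  9,  3, 11, 11, 10),
    ("CAMERA",        "I", 12, 12, 12, 12, 10,  7, 12, 12, 12),
    ("MRGSE",         "II", 1,  1,  1,  1,  2,  1,  1,  1,  1),
    ("GSEAP",         "II", 2,  2,  2,  2,  1,  2,  2,  2,  2),
    ("GAGE",          "II", 3,  3,  3,  3,  4,  3,  3,  3,  3),
    ("SIGPATHWAY_Q1", "II", 4,  4,  4,  4,  3,  4,  4,  4,  4),
]

_SCENARIO_COLS = [
    "overall", "small_n", "large_n", "small_set", "large_set",
    "paired", "unpaired", "small_effect", "large_effect",
]


def published_method_summary() -> pd.DataFrame:
    """Raw per-method metrics of the compendium evaluation, indexed by
    method id, with columns ``sampling_type``, ``category``, ``med_p``,
    ``med_rank`` and ``fp_pct_0.01``."""
    df = pd.DataFrame(
        _SUMMARY_ROWS,
        columns=["method_id", "sampling_type", "category",
                 "med_p", "med_rank", "fp_pct_0.01"],
    )
    return df.set_index("method_id")


def published_scenario_ranks() -> pd.DataFrame:
    """Per-category method ranks under the eight scenario splits."""
    df = pd.DataFrame(
        _SCENARIO_ROWS, columns=["method_id", "category", *_SCENARIO_COLS]
    )
    return df.set_index("method_id")
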