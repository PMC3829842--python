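"""Small shared helpers for the method implementations."""

from __future__ import annotations

import numpy as np


def set_indices(feature_ids: list[str], genes: list[str]) -> np.ndarray:
    """Row indices of the set's genes that are present on the array."""
    idx = {f: i for i, f in enumerate(feature_ids)}
    out = [idx[g] for g in genes if g in idx]
    if not out:
        raise ValueError("no set genes present in the dataset")
    return np.asarray(sorted(out), dtype=np.intp)


def tail_p(observed: float, nulls: np.ndarray, sided: str,
           include_observed: bool) -> float:
    """Permutation/randomization p-value.

    ``include_observed=True`` means the null bank enumerates the full
    randomization space including the observed assignment, so the exact
    p is the plain tail proportion; otherwise the (b+1)/(B+1) estimator
    is used, which also equals the exact p when the bank enumerates
    everything *except* the observed assignment.
    """
    nulls = np.asarray(nulls, dtype=float)
    # tolerance so that exact ties survive floating-point round-off in
    # independently computed null banks (matters for exhaustive nulls)
    eps = 1e-9 * max(1.0, abs(observed))
    if sided == "greater":
        b = np.sum(nulls >= observed - eps)
    elif sided == "less":
        b = np.sum(nulls <= observed + eps)
    elif sided == "two-sided":
        b = np.sum(np.abs(nulls) >= abs(observed) - eps)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    if include_observed:
        return float(b / nulls.size)
    return float((b + 1) / (nulls.size + 1))
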