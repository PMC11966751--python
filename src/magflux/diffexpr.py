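"""MAG-level differential expression between two sample groups.

A deliberately transparent count-based test: median-of-ratios
normalization (the convention of count-based DE tools), a pseudocount,
log2 fold change of group means, and a two-sample test on log2
normalized counts.  Downstream classification consumes only the sign of
the fold change and the significance tier (|log2FC| ≥ 1 and/or
P < 0.05), so no dispersion shrinkage is attempted.

The default p-value is a pooled-variance Student t on log2 normalized
counts, which is calibrated at the triplicate design used here; Welch
and label-permutation variants are available (note that an exact
permutation test on 3 + 3 samples cannot reach p < 0.1 and is therefore
useless at the 5% level).
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "size_factors",
    "normalized_counts",
    "de_test",
    "assign_tier",
    "TIERS",
]

TIERS = ("NS", "fc_only", "p_only", "both")

PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, geometric mean normalized to 1.

    For each sample: the median over MAGs (restricted to MAGs with
    nonzero counts in every sample) of count divided by the MAG's
    geometric-mean count.  If no MAG is nonzero everywhere, falls back
    to total-count scaling with a warning.
    """
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        logx = np.log(x[all_pos])
        log_geo = logx.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logx - log_geo, axis=0))
    else:
        warnings.warn(
            "no MAG has nonzero counts in every sample; "
            "falling back to total-count size factors",
            stacklevel=2,
        )
        totals = x.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("a sample has zero total counts")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def normalized_counts(
    counts: pd.DataFrame, factors: pd.Series | None = None
) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def assign_tier(
    log2fc: float, p: float, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> str:
    """Significance tier under the |log2FC| ≥ 1 and/or P < 5% rule."""
    fc = abs(log2fc) >= lfc_threshold
    sig = p < alpha
    if fc and sig:
        return "both"
    if fc:
        return "fc_only"
    if sig:
        return "p_only"
    return "NS"


def _permutation_p(
    logvals: np.ndarray, n_a: int, seed: int, n_perm: int
) -> np.ndarray:
    """Two-sided label-permutation p for the difference of group means.

    Exact enumeration of label assignments when feasible (p includes
    the identity permutation), otherwise ``n_perm`` random draws with
    the add-one convention.
    """
    n = logvals.shape[1]
    obs = logvals[:, n_a:].mean(axis=1) - logvals[:, :n_a].mean(axis=1)
    n_comb = math.comb(n, n_a)
    if n_comb <= 20000:
        idx = np.array(list(itertools.combinations(range(n), n_a)))
        count = np.zeros(logvals.shape[0])
        total = idx.shape[0]
        for rows in idx:
            mask = np.zeros(n, dtype=bool)
            mask[list(rows)] = True
            stat = logvals[:, ~mask].mean(axis=1) - logvals[:, mask].mean(axis=1)
            count += np.abs(stat) >= np.abs(obs) - 1e-12
        return count / total
    rng = np.random.default_rng(seed)
    count = np.zeros(logvals.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(n)
        a, b = perm[:n_a], perm[n_a:]
        stat = logvals[:, b].mean(axis=1) - logvals[:, a].mean(axis=1)
        count += np.abs(stat) >= np.abs(obs) - 1e-12
    return (1.0 + count) / (1.0 + n_perm)


def _t_p(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Vectorized two-sided t p-values with a degenerate-variance guard."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    same_mean = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(zero_var & same_mean, 1.0, p)
    p = np.where(zero_var & ~same_mean, 0.0, p)
    return p


def de_test(
    counts: pd.DataFrame,
    group_a: Sequence,
    group_b: Sequence,
    seed: int = 0,
    method: str = "student",
    n_perm: int = 10000,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential expression of group B over group A.

    Parameters
    ----------
    counts : DataFrame
        Integer mapped-read counts, MAGs × samples.
    group_a, group_b : sequences of column labels
        Disjoint sample groups, each with at least two samples.
    method : {"student", "welch", "permutation"}
        Test on log2 normalized counts.  ``student`` (pooled variance)
        is the default.
    seed : int
        Used only by the sampled permutation test.

    Returns a frame with ``mag_id``, ``base_mean``, ``log2fc`` (B over
    A), ``p_value``, BH-adjusted ``q_value``, ``tier``, and
    volcano-plot coordinates (``log2fc``, ``neg_log10_p``).
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples")
    for col in group_a + group_b:
        if col not in counts.columns:
            raise KeyError(f"sample {col!r} not in count table")
    if method not in ("student", "welch", "permutation"):
        raise ValueError(f"unknown method {method!r}")

    sub = counts[group_a + group_b]
    norm = normalized_counts(sub).to_numpy(dtype=float) + PSEUDOCOUNT
    n_a = len(group_a)
    a, b = norm[:, :n_a], norm[:, n_a:]
    log2fc = np.log2(b.mean(axis=1) / a.mean(axis=1))
    log_a, log_b = np.log2(a), np.log2(b)
    if method == "permutation":
        p = _permutation_p(np.hstack([log_a, log_b]), n_a, seed=seed, n_perm=n_perm)
    else:
        p = _t_p(log_a, log_b, equal_var=(method == "student"))
    p = np.clip(p, 0.0, 1.0)
    q = stats.false_discovery_control(p)
    out = pd.DataFrame(
        {
            "mag_id": sub.index,
            "base_mean": norm.mean(axis=1) - PSEUDOCOUNT,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "tier": [
                assign_tier(fc, pv, lfc_threshold, alpha)
                for fc, pv in zip(log2fc, p)
            ],
        }
    )
    out["neg_log10_p"] = -np.log10(np.maximum(out["p_value"], 1e-300))
    return out
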