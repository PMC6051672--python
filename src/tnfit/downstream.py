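"""Downstream screen-validation statistics.

Two independent assays follow up the genetic screen:

* spectral-count proteomics — per-protein fold change (mutant/WT) with a
  two-sample t-test on normalized counts, to find proteins accumulating
  in a mutant background;
* cell-length distributions — division-blocked (filamentous) cells are
  scored as the proportion longer than a threshold of three typical cell
  lengths (6.75 um for a 2.25 um cell), with the binomial-proportion SD
  and a one-tailed two-proportion Z-test between strains.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_counts",
    "differential_abundance",
    "proportion_long",
    "ztest_proportions_onetailed",
]


def normalize_counts(raw: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its total matches the across-sample mean total.

    Standard total-count normalization for spectral counts: sample ``j``
    is multiplied by ``mean(totals) / total_j``.  Raises on an all-zero
    sample (no scale is defined).
    """
    if (raw.values < 0).any():
        raise ValueError("raw counts must be non-negative")
    totals = raw.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    return raw * (totals.mean() / totals)


def differential_abundance(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-protein fold change and t-test p-value between two groups.

    ``fold_change = mean(group_b) / mean(group_a)`` (B the mutant, A the
    wild type).  The p-value is a two-sample t-test (pooled variance by
    default; ``equal_var=False`` for Welch).  Proteins identical across
    both groups (zero variance, zero difference) get p = 1 by convention;
    a zero group-A mean yields an infinite fold change, flagged but kept.

    Returns a DataFrame indexed by protein with columns ``mean_a, mean_b,
    fold_change, p_value, significant, infinite_fold``; the attribute
    ``attrs['n_significant']`` and ``attrs['n_significant_up']`` carry the
    headline counts (p < alpha; p < alpha and fold > 1).
    """
    a = matrix[list(group_a)]
    b = matrix[list(group_b)]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_b / mean_a
    infinite = np.isinf(fold.values) | (mean_a.values == 0) & (mean_b.values > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(b.values, a.values, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    p[degenerate] = 1.0  # zero variance and zero difference: no evidence
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold,
            "p_value": p,
            "significant": p < alpha,
            "infinite_fold": infinite,
        },
        index=matrix.index,
    )
    out.attrs["n_significant"] = int(out["significant"].sum())
    out.attrs["n_significant_up"] = int(
        (out["significant"] & (out["fold_change"] > 1)).sum()
    )
    return out


def proportion_long(
    lengths: Sequence[float], threshold: float = 6.75
) -> tuple[float, float, int]:
    """Proportion of cells strictly longer than ``threshold`` um.

    Returns ``(p, sd, n)`` with the binomial-proportion standard deviation
    ``sd = sqrt(p (1 - p) / n)``.
    """
    v = np.asarray(lengths, dtype=float)
    if v.size == 0:
        raise ValueError("empty length sample")
    if (v <= 0).any():
        raise ValueError("cell lengths must be positive")
    n = int(v.size)
    p = float((v > threshold).mean())
    sd = float(np.sqrt(p * (1.0 - p) / n))
    return p, sd, n


def ztest_proportions_onetailed(
    p1: float, n1: int, p2: float, n2: int, pooled: bool = True
) -> tuple[float, float]:
    """One-tailed two-proportion Z-test for the alternative p2 > p1.

    z = (p2 - p1) / sqrt(pbar (1 - pbar) (1/n1 + 1/n2)) with pbar the
    pooled proportion (``pooled=False`` uses the unpooled SE).  Returns
    ``(p_value, z)`` with the upper-tail normal p-value.  Degenerate
    pooled proportions (0 or 1) give p = 0.5 when p1 == p2 and raise
    otherwise.
    """
    for p, n in ((p1, n1), (p2, n2)):
        if not 0 <= p <= 1:
            raise ValueError(f"proportion {p} outside [0, 1]")
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
    pbar = (p1 * n1 + p2 * n2) / (n1 + n2)
    if pooled:
        var = pbar * (1 - pbar) * (1 / n1 + 1 / n2)
    else:
        var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if var == 0:
        if p1 == p2:
            return 0.5, 0.0
        raise ValueError("degenerate proportions: zero variance with p1 != p2")
    z = (p2 - p1) / np.sqrt(var)
    return float(stats.norm.sf(z)), float(z)
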