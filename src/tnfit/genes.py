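"""Gene-level inference: aggregate insertion relative fitness per gene,
test deviation from neutrality, and select screen candidates.

A gene's relative fitness is the arithmetic mean of the per-insertion
``w_rel`` values falling inside its annotated body; the 95% CI is the usual
one-sample t interval and the p-value a two-sided one-sample t-test against
the neutral value 1.  P-values are corrected per growth period with the
Benjamini-Hochberg step-up procedure.  Insertions between genes are pooled
into indexed intergenic units ("ig" labels) so the correction spans every
tested unit.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneFeature

logger = logging.getLogger(__name__)

__all__ = [
    "map_insertions_to_genes",
    "gene_relative_fitness",
    "test_vs_neutral",
    "bh_adjust",
    "gene_fitness_table",
    "select_candidates",
]


def map_insertions_to_genes(
    sites: pd.DataFrame | Sequence[tuple],
    annotation: Sequence[GeneFeature],
    label_intergenic: bool = True,
) -> pd.DataFrame:
    """Assign insertion sites to genes by coordinate containment.

    A site at ``position`` maps to gene ``g`` iff ``g.start <= position <=
    g.end`` on the same replicon (strand is ignored).  Sites inside several
    overlapping genes get one row per gene (with a warning).  Sites covered
    by no gene are labelled ``ig_<k>``, numbering the intergenic intervals
    left to right per replicon, or dropped if ``label_intergenic`` is False.

    Parameters
    ----------
    sites : DataFrame with columns replicon/position (extra columns kept),
        or a sequence of (replicon, position[, strand]) tuples.
    annotation : gene features.

    Returns the input rows with an added ``gene_id`` column (possibly
    duplicated rows for overlapping genes).
    """
    if not isinstance(sites, pd.DataFrame):
        sites = pd.DataFrame(
            [t[:2] for t in sites], columns=["replicon", "position"]
        )
    trees: dict[str, IntervalTree] = {}
    by_rep: dict[str, list[GeneFeature]] = {}
    for g in annotation:
        # IntervalTree is half-open; +1 makes the gene end inclusive
        trees.setdefault(g.replicon, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
        by_rep.setdefault(g.replicon, []).append(g)

    ig_trees: dict[str, IntervalTree] = {}
    if label_intergenic:
        for rep, genes in by_rep.items():
            tree = IntervalTree()
            edges: list[int] = []
            for g in sorted(genes, key=lambda g: (g.start, g.end)):
                edges.append(g.start)
                edges.append(g.end)
            prev = 1
            k = 0
            for g in sorted(genes, key=lambda g: (g.start, g.end)):
                if g.start > prev:
                    k += 1
                    tree.addi(prev, g.start, f"ig_{k}")
                prev = max(prev, g.end + 1)
            k += 1
            tree.addi(prev, 2**40, f"ig_{k}")  # tail after the last gene
            ig_trees[rep] = tree

    reps = sites["replicon"].to_numpy()
    poss = sites["position"].to_numpy()
    row_idx: list[int] = []
    gene_ids: list[str] = []
    empty_tree = IntervalTree()
    warned_overlap = False
    for i in range(len(sites)):
        rep, pos = reps[i], int(poss[i])
        hits = sorted(iv.data for iv in trees.get(rep, empty_tree)[pos])
        if len(hits) > 1 and not warned_overlap:
            logger.warning(
                "site %s:%d lies inside %d overlapping genes; assigned to all",
                rep,
                pos,
                len(hits),
            )
            warned_overlap = True
        if not hits:
            if not label_intergenic:
                continue
            ig_hits = ig_trees.get(rep)
            hits = [next(iter(ig_hits[pos])).data if ig_hits and ig_hits[pos] else "ig_0"]
        for gid in hits:
            row_idx.append(i)
            gene_ids.append(gid)
    out = sites.iloc[row_idx].reset_index(drop=True)
    out["gene_id"] = pd.Series(gene_ids, dtype=object)
    return out


def gene_relative_fitness(
    values: Sequence[float], min_insertions: int = 3
) -> tuple[float, tuple[float, float], int]:
    """Mean relative fitness of one gene with its 95% confidence interval.

    CI = mean +/- t(0.975, n-1) * sd / sqrt(n).  Genes with fewer than
    ``min_insertions`` usable insertions carry insufficient data and raise
    ``ValueError`` (callers exclude them).

    Returns ``(mean, (ci_low, ci_high), n)``.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < min_insertions:
        raise ValueError(
            f"insufficient data: {n} insertions < min_insertions={min_insertions}"
        )
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        return mean, (mean, mean), n
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return mean, (mean - half, mean + half), n


def test_vs_neutral(values: Sequence[float], null_mean: float = 1.0) -> tuple[float, bool]:
    """Two-sided one-sample t-test of mean relative fitness against 1.

    Zero-variance samples are assigned p = 1 by convention and flagged
    (``(p, degenerate)`` is returned) — with no spread there is no evidence
    against neutrality at any mean, only a warning sign about the data.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a t-test")
    if np.ptp(v) == 0.0:
        return 1.0, True
    res = stats.ttest_1samp(v, popmean=null_mean)
    return float(res.pvalue), False


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_i = min_{j >= rank(i)} (p_(j) * m / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def gene_fitness_table(
    rel_fitness: pd.DataFrame,
    annotation: Sequence[GeneFeature],
    min_insertions: int = 3,
    include_intergenic: bool = True,
) -> pd.DataFrame:
    """Build the per-gene relative-fitness table from per-insertion results.

    ``rel_fitness`` is the output of
    :func:`tnfit.fitness.fitness_per_period`; excluded rows (missing or
    control-extinct sites) are dropped before aggregation.  BH adjustment is
    performed within each growth period over all tested units (genes and,
    if ``include_intergenic``, intergenic "ig" regions).

    Returns a DataFrame with columns ``gene_id, growth_period,
    n_insertions, mean_relative_fitness, ci95_low, ci95_high, p_value,
    p_adj, zero_variance``.
    """
    usable = rel_fitness[~rel_fitness["excluded"] & rel_fitness["w_rel"].notna()]
    if usable.empty:
        return pd.DataFrame(
            columns=[
                "gene_id",
                "growth_period",
                "n_insertions",
                "mean_relative_fitness",
                "ci95_low",
                "ci95_high",
                "p_value",
                "p_adj",
                "zero_variance",
            ]
        )
    sites = usable[["replicon", "position"]].drop_duplicates()
    assigned = map_insertions_to_genes(
        sites, annotation, label_intergenic=include_intergenic
    )
    merged = usable.merge(assigned, on=["replicon", "position"])
    rows = []
    for (gid, period), grp in merged.groupby(["gene_id", "growth_period"], sort=True):
        vals = grp["w_rel"].values
        if len(vals) < min_insertions:
            continue
        mean, (lo, hi), n = gene_relative_fitness(vals, min_insertions)
        p, degenerate = test_vs_neutral(vals)
        rows.append(
            {
                "gene_id": gid,
                "growth_period": period,
                "n_insertions": n,
                "mean_relative_fitness": mean,
                "ci95_low": lo,
                "ci95_high": hi,
                "p_value": p,
                "zero_variance": degenerate,
            }
        )
    if not rows:
        warnings.warn("no gene reached the min_insertions threshold")
        return gene_fitness_table(rel_fitness.iloc[0:0], annotation)
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    for period, grp in table.groupby("growth_period"):
        table.loc[grp.index, "p_adj"] = bh_adjust(grp["p_value"].values)
    cols = [
        "gene_id",
        "growth_period",
        "n_insertions",
        "mean_relative_fitness",
        "ci95_low",
        "ci95_high",
        "p_value",
        "p_adj",
        "zero_variance",
    ]
    return table[cols].sort_values(
        ["growth_period", "mean_relative_fitness", "p_adj", "gene_id"],
        kind="mergesort",
    ).reset_index(drop=True)


def select_candidates(
    gene_table: pd.DataFrame,
    growth_period: int = 2,
    top_n: int = 200,
    alpha: float = 0.01,
    include_intergenic: bool = False,
) -> pd.DataFrame:
    """The screen's candidate list: lowest-fitness significant genes.

    Restricts the gene table to one growth period and adjusted p-value
    below ``alpha``, sorts ascending by mean relative fitness (ties broken
    by smaller p_adj, then lexicographic gene_id) and returns the first
    ``top_n`` rows (fewer if fewer qualify).  Intergenic units are excluded
    from candidate lists by default.
    """
    sub = gene_table[gene_table["growth_period"] == growth_period]
    if not include_intergenic:
        sub = sub[~sub["gene_id"].astype(str).str.startswith("ig_")]
    sub = sub[sub["p_adj"] < alpha]
    sub = sub.sort_values(
        ["mean_relative_fitness", "p_adj", "gene_id"], kind="mergesort"
    )
    return sub.head(top_n).reset_index(drop=True)
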