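"""Cross-screen comparison: Venn-style overlap of candidate gene sets.

Candidate lists from independent screens (e.g. three DNA-damaging agents)
are intersected to find genes generally required under the stress class.
Gene identity across screens is by exact gene_id string match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["ScreenResult", "overlap", "write_overlap_report"]


@dataclass
class ScreenResult:
    """Candidate gene set of one screen, with its full ranked table."""

    experiment_id: str
    candidates: frozenset[str]
    gene_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.candidates = frozenset(self.candidates)
        if self.gene_table is not None:
            known = set(self.gene_table["gene_id"].astype(str))
            stray = self.candidates - known
            if stray:
                raise ValueError(
                    f"screen {self.experiment_id!r}: candidates not in its "
                    f"ranked table: {sorted(stray)[:5]}..."
                )


@dataclass
class OverlapResult:
    """Exclusive Venn regions plus all plain intersections of >= 2 screens."""

    experiment_ids: tuple[str, ...]
    #: exclusive region -> genes only in exactly that set of screens
    regions: dict[frozenset, frozenset] = field(default_factory=dict)
    #: subset of >=2 screens -> plain (non-exclusive) intersection
    intersections: dict[frozenset, frozenset] = field(default_factory=dict)

    @property
    def full_intersection(self) -> frozenset:
        if len(self.experiment_ids) < 2:
            raise ValueError("need >= 2 screens")
        return self.intersections[frozenset(self.experiment_ids)]

    def region(self, *experiment_ids: str) -> frozenset:
        """Genes exclusively in the given screens and no others."""
        return self.regions[frozenset(experiment_ids)]


def overlap(screens: Iterable[ScreenResult | tuple]) -> OverlapResult:
    """Venn decomposition of candidate sets from >= 2 screens.

    Accepts ScreenResult objects or plain ``(experiment_id, gene_set)``
    pairs.  For every non-empty combination of screens the *exclusive*
    region (genes in exactly those screens) is computed, plus the plain
    intersection for every combination of two or more.
    """
    sets: dict[str, frozenset] = {}
    for s in screens:
        if isinstance(s, ScreenResult):
            eid, genes = s.experiment_id, s.candidates
        else:
            eid, genes = s
        if eid in sets:
            raise ValueError(f"duplicate experiment id {eid!r}")
        sets[eid] = frozenset(genes)
    ids = tuple(sets)
    if len(ids) < 2:
        raise ValueError("need >= 2 screens for an overlap")
    result = OverlapResult(experiment_ids=ids)
    for r in range(1, len(ids) + 1):
        for combo in combinations(ids, r):
            inside = frozenset.intersection(*(sets[i] for i in combo))
            outside = frozenset.union(
                *(sets[i] for i in ids if i not in combo), frozenset()
            )
            result.regions[frozenset(combo)] = inside - outside
            if r >= 2:
                result.intersections[frozenset(combo)] = inside
    return result


def write_overlap_report(result: OverlapResult, path: str | Path) -> pd.DataFrame:
    """Write the overlap as a TSV: one row per exclusive Venn region.

    Columns: ``screens`` ('+'-joined ids), ``n_screens``, ``n_genes``,
    ``genes`` (comma-joined, sorted).  Rows are ordered by descending
    number of screens, then by screen ids, so the full intersection comes
    first — the screens' headline result.
    """
    rows = []
    order = {eid: k for k, eid in enumerate(result.experiment_ids)}
    for combo, genes in result.regions.items():
        ids = sorted(combo, key=order.get)
        rows.append(
            {
                "screens": "+".join(ids),
                "n_screens": len(ids),
                "n_genes": len(genes),
                "genes": ",".join(sorted(genes)),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["n_screens", "screens"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    return df
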