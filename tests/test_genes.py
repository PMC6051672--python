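"""Gene-level aggregation: mapping, t statistics, BH, candidate selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnfit.genes import (
    bh_adjust,
    gene_fitness_table,
    gene_relative_fitness,
    map_insertions_to_genes,
    select_candidates,
    test_vs_neutral as neutrality_pvalue,
)
from tnfit.io import GeneFeature


GENES = [
    GeneFeature("gA", "gA", "chr1", 100, 400, "+"),
    GeneFeature("gB", "gB", "chr1", 600, 900, "-"),
]


def bh_oracle(p):
    """Exhaustive-min BH definition: adj_i = min over j >= rank(i) of p_(j)*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_pos, i in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestMapping:
    def _map(self, positions, **kw):
        sites = pd.DataFrame({"replicon": "chr1", "position": positions})
        return map_insertions_to_genes(sites, GENES, **kw)

    def test_inside_gene(self):
        out = self._map([150])
        assert list(out["gene_id"]) == ["gA"]

    def test_inclusive_boundaries(self):
        out = self._map([100, 400, 401, 99])
        assert list(out["gene_id"]) == ["gA", "gA", "ig_2", "ig_1"]

    def test_overlapping_genes_assigned_to_all(self, caplog):
        genes = GENES + [GeneFeature("gC", "gC", "chr1", 300, 700, "+")]
        sites = pd.DataFrame({"replicon": "chr1", "position": [350]})
        with caplog.at_level("WARNING"):
            out = map_insertions_to_genes(sites, genes)
        assert sorted(out["gene_id"]) == ["gA", "gC"]
        assert "overlapping" in caplog.text

    def test_intergenic_numbering_left_to_right(self):
        out = self._map([50, 500, 950])
        assert list(out["gene_id"]) == ["ig_1", "ig_2", "ig_3"]

    def test_drop_intergenic_option(self):
        out = self._map([50, 150], label_intergenic=False)
        assert list(out["gene_id"]) == ["gA"]


class TestGeneFitness:
    def test_closed_form_ci(self):
        # one-sample t interval: t(0.975, 2) = 4.3027, sd = 0.1
        mean, (lo, hi), n = gene_relative_fitness([0.8, 0.9, 1.0])
        assert mean == pytest.approx(0.9)
        assert lo == pytest.approx(0.6516, abs=2e-4)
        assert hi == pytest.approx(1.1484, abs=2e-4)
        assert n == 3

    def test_zero_variance_zero_width(self):
        mean, (lo, hi), _ = gene_relative_fitness([1, 1, 1, 1])
        assert mean == lo == hi == 1.0

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            gene_relative_fitness([0.5], min_insertions=3)


class TestNeutralityTest:
    def test_closed_form_small_sample(self):
        # t = -1.7321, df = 2: two-sided p = 1 - t/sqrt(2+t^2) = 0.2254
        p, flag = neutrality_pvalue([0.8, 0.9, 1.0])
        assert p == pytest.approx(0.2254, abs=2e-4)
        assert not flag

    def test_symmetric_about_one(self):
        p, _ = neutrality_pvalue([0.9, 1.1, 0.8, 1.2])
        assert p == pytest.approx(1.0)

    def test_zero_variance_convention(self):
        p, flag = neutrality_pvalue([0.5, 0.5, 0.5, 0.5])
        assert p == 1.0 and flag


class TestBH:
    def test_worked_example(self):
        adj = bh_adjust([0.001, 0.01, 0.03, 0.04])
        assert np.allclose(adj, [0.004, 0.02, 0.04, 0.04])

    def test_all_ones_and_singleton(self):
        assert np.allclose(bh_adjust([1, 1, 1]), 1)
        assert np.allclose(bh_adjust([0.37]), [0.37])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50)
    )
    def test_matches_exhaustive_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40))
    def test_adjusted_at_least_raw_and_monotone(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()


def _gene_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "growth_period",
            "n_insertions",
            "mean_relative_fitness",
            "ci95_low",
            "ci95_high",
            "p_value",
            "p_adj",
        ],
    )


class TestSelectCandidates:
    def test_caps_at_top_n_lowest_means(self):
        rows = [
            (f"g{i:03d}", 2, 5, 0.3 + i * 0.001, 0, 1, 1e-5, 1e-4) for i in range(300)
        ]
        out = select_candidates(_gene_table(rows), top_n=200)
        assert len(out) == 200
        assert out["mean_relative_fitness"].max() < 0.3 + 200 * 0.001

    def test_fewer_qualify_than_top_n(self):
        rows = [(f"g{i}", 2, 5, 0.5, 0, 1, 1e-5, 1e-4) for i in range(50)]
        rows += [(f"h{i}", 2, 5, 0.4, 0, 1, 0.5, 0.9) for i in range(100)]
        out = select_candidates(_gene_table(rows), top_n=200, alpha=0.01)
        assert len(out) == 50

    def test_tie_break_by_p_adj_then_gene_id(self):
        rows = [
            ("gB", 2, 5, 0.5, 0, 1, 1e-5, 1e-3),
            ("gA", 2, 5, 0.5, 0, 1, 1e-5, 1e-3),
            ("gC", 2, 5, 0.5, 0, 1, 1e-6, 1e-4),
        ]
        out = select_candidates(_gene_table(rows), top_n=2)
        assert list(out["gene_id"]) == ["gC", "gA"]

    def test_other_period_ignored(self):
        rows = [("g1", 1, 5, 0.2, 0, 1, 1e-5, 1e-4), ("g2", 2, 5, 0.4, 0, 1, 1e-5, 1e-4)]
        out = select_candidates(_gene_table(rows), growth_period=2)
        assert list(out["gene_id"]) == ["g2"]


class TestGeneFitnessTable:
    def test_pipeline_table_invariants(self, small_fit):
        _, res = small_fit
        g = res.gene_fitness
        assert (g["ci95_low"] <= g["mean_relative_fitness"] + 1e-12).all()
        assert (g["mean_relative_fitness"] <= g["ci95_high"] + 1e-12).all()
        assert g["p_value"].between(0, 1).all()
        assert (g["p_adj"] >= g["p_value"] - 1e-15).all()
        assert (g["n_insertions"] >= 3).all()

    def test_sensitive_genes_rank_lowest(self, small_fit):
        model, res = small_fit
        sens = model.gene_truth.query("label == 'sensitive'")["gene_id"]
        cand = res.candidates(growth_period=2, top_n=200, alpha=0.01)
        assert set(sens) <= set(cand["gene_id"])
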