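"""The per-insertion fitness model: identities, oracle agreement, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tnfit
from tnfit.fitness import (
    compute_generations,
    filter_insertions,
    fitness_per_period,
    insertion_fitness,
    insertion_fitness_vec,
    insertion_frequency,
    relative_fitness,
)
from conftest import make_counts


class TestGenerations:
    @pytest.mark.parametrize(
        "N0,Nf,G,d",
        [
            (5e6, 4e7, 3.0, 8.0),
            (1e6, 1e6, 0.0, 1.0),
            (1e6, 1e8, np.log2(100), 100.0),
        ],
    )
    def test_examples(self, N0, Nf, G, d):
        g, dd = compute_generations(N0, Nf)
        assert g == pytest.approx(G)
        assert dd == pytest.approx(d)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            compute_generations(0, 1e7)


class TestFrequency:
    def test_basic_and_absent(self):
        sc = make_counts({("chr1", 1, "+"): 10, ("chr1", 2, "+"): 990})
        assert insertion_frequency(sc, ("chr1", 1, "+")) == pytest.approx(0.01)
        assert insertion_frequency(sc, ("chr1", 99, "+")) == 0.0

    def test_monopolised_sample_warns(self, caplog):
        sc = make_counts({("chr1", 1, "+"): 50})
        with caplog.at_level("WARNING"):
            assert insertion_frequency(sc, ("chr1", 1, "+")) == 1.0
        assert "rare-mutant" in caplog.text


class TestInsertionFitness:
    def test_unchanged_frequency_is_exactly_neutral(self):
        w, ext = insertion_fitness(0.001, 0.001, 100)
        assert w == 1.0 and not ext

    def test_doubling_rare_mutant(self):
        # ln(0.002*100/0.001)/ln(0.998*100/0.999) evaluated independently
        w, _ = insertion_fitness(0.001, 0.002, 100)
        assert w == pytest.approx(1.15077, abs=1e-4)

    def test_extinct_convention(self):
        w, ext = insertion_fitness(0.001, 0.0, 100)
        assert w == 0.0 and ext

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="d="):
            insertion_fitness(0.001, 0.002, 1.0)
        with pytest.raises(ValueError, match="F0"):
            insertion_fitness(0.0, 0.002, 100)

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(
        f0=st.floats(1e-8, 0.5),
        d=st.floats(1.01, 1e4),
    )
    def test_neutrality_identity(self, f0, d):
        w, _ = insertion_fitness(f0, f0, d)
        assert w == 1.0

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        f0=st.floats(1e-6, 0.2),
        d=st.floats(1.5, 1e3),
        data=st.data(),
    )
    def test_monotone_in_ff(self, f0, d, data):
        # Monotonicity holds on the model's domain: the non-mutant rest of
        # the population must itself expand, Ff < 1 - (1 - F0)/d.
        ff_max = 0.95 * (1.0 - (1.0 - f0) / d)
        ff1 = data.draw(st.floats(1e-8, ff_max))
        ff2 = data.draw(st.floats(1e-8, ff_max))
        lo, hi = sorted([ff1, ff2])
        if hi - lo < 1e-6 * hi:  # below float resolution of the log ratio
            return
        w_lo, _ = insertion_fitness(f0, lo, d)
        w_hi, _ = insertion_fitness(f0, hi, d)
        assert w_hi > w_lo

    def test_rare_mutant_oracle(self):
        """Invert a deterministic passage of a rare mutant in a neutral pool."""
        d = 100.0
        for w_true in (0.2, 0.5, 0.8, 1.0, 1.2):
            f0 = 1e-4
            n0_mut, n0_rest = f0, 1 - f0
            nf_mut, nf_rest = n0_mut * d**w_true, n0_rest * d
            ff = nf_mut / (nf_mut + nf_rest)
            d_real = (nf_mut + nf_rest) / 1.0
            w_hat, _ = insertion_fitness(f0, ff, d_real)
            assert abs(w_hat - w_true) <= 0.01 * w_true

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(0)
        f0 = rng.uniform(1e-6, 0.1, 50)
        ff = rng.uniform(0, 0.1, 50)
        ff[::7] = 0.0
        w_vec, ext = insertion_fitness_vec(f0, ff, 8.0, floor_at_zero=False)
        for i in range(50):
            w_s, e_s = insertion_fitness(f0[i], ff[i], 8.0)
            assert w_vec[i] == pytest.approx(w_s)
            assert ext[i] == e_s

    def test_vectorised_floors_negative_estimates(self):
        # frequency falls faster than dilution -> raw estimate below 0
        w, _ = insertion_fitness_vec(np.array([1e-3]), np.array([1e-5]), 2.0)
        assert w[0] == 0.0


class TestRelativeFitness:
    @pytest.mark.parametrize(
        "wt,wc,expected", [(0.6, 1.2, 0.5), (0.9, 0.9, 1.0), (0.0, 1.0, 0.0)]
    )
    def test_examples(self, wt, wc, expected):
        assert relative_fitness(wt, wc) == pytest.approx(expected)

    def test_control_extinct_rejected(self):
        with pytest.raises(ValueError, match="control"):
            relative_fitness(0.5, 0.0)


class TestFilter:
    def test_strictly_greater_than(self):
        sc = make_counts({("c", 1, "+"): 10, ("c", 2, "+"): 11, ("c", 3, "+"): 500})
        kept = filter_insertions(sc, 10)
        assert set(kept.get_level_values("position")) == {2, 3}

    def test_threshold_zero_keeps_any_read(self):
        sc = make_counts({("c", 1, "+"): 1, ("c", 2, "+"): 3})
        assert len(filter_insertions(sc, 0)) == 2

    def test_empty_sample(self):
        sc = make_counts({})
        assert len(filter_insertions(sc, 10)) == 0


class TestFitnessPerPeriod:
    def test_noise_free_recovery(self):
        """Infinite-depth limit: the pipeline recovers true fitness exactly
        (neutral sites at w_rel=1, a W=0.5 gene near 0.5 in every period)."""
        # ~2% of the insertion pool deleterious, as in the emulated design;
        # w_rel is fitness relative to the population average, so a larger
        # deleterious mass would visibly shift the neutral baseline
        cfg = tnfit.SimConfig(
            seed=5,
            n_genes=50,
            n_insertions=2500,
            read_depth=100_000_000,
            n_sensitive_genes=1,
            n_replicates=1,
        )
        sim = tnfit.simulate_experiment(cfg)
        rel = fitness_per_period(sim.dataset, min_control_reads=10)
        merged = rel.merge(
            sim.truth, on=["replicon", "position", "strand"], how="left"
        )
        merged = merged[~merged["excluded"]]
        neutral = merged[merged["w_treatment"] == 1.0]
        sensitive = merged[merged["w_treatment"] == 0.5]
        assert len(sensitive) > 50
        # per-site estimates track truth; means are recovered tightly
        assert np.allclose(neutral["w_rel"], 1.0, atol=0.05)
        assert np.allclose(sensitive["w_rel"], 0.5, atol=0.05)
        for p in (1, 2, 3):
            assert neutral.loc[
                neutral["growth_period"] == p, "w_rel"
            ].mean() == pytest.approx(1.0, abs=0.01)
            assert sensitive.loc[
                sensitive["growth_period"] == p, "w_rel"
            ].mean() == pytest.approx(0.5, abs=0.02)

    def test_filter_applied_per_period(self, small_sim):
        rel = fitness_per_period(small_sim.dataset, min_control_reads=10)
        # a site may pass in one period and fail in another; per-period row sets differ
        sets = {
            p: set(map(tuple, g[["replicon", "position", "strand"]].values))
            for p, g in rel.groupby("growth_period")
        }
        assert set(sets) == {1, 2, 3}
        assert all(len(s) > 0 for s in sets.values())

    def test_missing_period_skipped_with_warning(self, small_sim, caplog):
        ds = small_sim.dataset
        pruned = tnfit.ScreenDataset(
            samples=[s for s in ds.samples if s.growth_period != 3],
            growth_records=ds.growth_records,
            annotation=ds.annotation,
            genome_length=ds.genome_length,
        )
        with caplog.at_level("WARNING"):
            rel = fitness_per_period(pruned)
        # timepoint 3 is the end of period 2 and the start of period 3
        assert set(rel["growth_period"]) == {1}
        assert "skipped" in caplog.text

    def test_per_replicate_mode_close_to_pooled(self, small_sim):
        pooled = fitness_per_period(small_sim.dataset, pool_replicates=True)
        per_rep = fitness_per_period(small_sim.dataset, pool_replicates=False)
        m = pooled.merge(
            per_rep,
            on=["growth_period", "replicon", "position", "strand"],
            suffixes=("_pool", "_rep"),
        )
        ok = m[~m["excluded_pool"] & ~m["excluded_rep"]]
        assert len(ok) > 1000
        assert np.corrcoef(ok["w_rel_pool"], ok["w_rel_rep"])[0, 1] > 0.9
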