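"""Synthetic Tn-seq screens with known ground truth.

The generator emulates the study design end to end: a dense transposon
library (~120,000 distinct insertion sites, uniform over the genome except
for clustered essential regions), outgrowth of a shared starter culture,
a split into paired control and treatment arms, three serial growth
periods with recorded start/end viable-cell counts, and multinomial
sequencing noise at a fixed read depth per sample.

Growth is deterministic and exponential: over a period with nominal
population expansion ``d``, a mutant with true fitness ``W`` multiplies
its cell count by ``d**W``.  The recorded viable counts are the *realised*
totals, so the expansion factor the pipeline measures reflects the fitness
mixture rather than the nominal ``d``.  Sequencing is the only stochastic
step by default; an optional bottleneck resampling between periods mimics
the dilution of real serial passaging.

Every simulated site carries a truth row (its true W under control and
treatment) and every gene a label in {neutral, sensitive, essential},
enabling parameter-recovery and false-discovery tests of the full
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    GeneFeature,
    GrowthRecord,
    SampleCounts,
    ScreenDataset,
    SITE_INDEX,
    write_count_table,
    write_gff3,
    write_viable_counts,
)

__all__ = [
    "SimConfig",
    "SimulatedScreen",
    "simulate_genome",
    "simulate_library",
    "simulate_passage",
    "sample_reads",
    "simulate_experiment",
    "simulate_multi_screen",
    "simulate_null_spectral_matrix",
]

_TOKEN_CODES = {
    "genome": 0,
    "sites": 1,
    "library": 2,
    "starter": 3,
    "control": 4,
    "treatment": 5,
    "bottleneck": 6,
    "spectral": 7,
    "screen": 8,
    "sensitive": 9,
}


def _rng(seed: int, *tokens) -> np.random.Generator:
    """Child generator from a stable hash of (seed, tokens)."""
    codes = [int(seed) & 0x7FFFFFFF]
    for t in tokens:
        codes.append(_TOKEN_CODES[t] if isinstance(t, str) else (int(t) & 0x7FFFFFFF))
    return np.random.default_rng(np.random.SeedSequence(codes))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated screen.

    Defaults mirror the screen design being emulated: ~120,000 distinct
    insertions over a ~1 Mb genome of 1,000 genes, two clustered essential
    regions, 20 treatment-sensitive genes at true relative fitness 0.5,
    three growth periods of 3 generations each (expansion factor 8, as in
    a back-diluted outgrowth from 5e6 to 4e7 viable cells), and 5 million
    reads per sequencing sample with two sequencing replicates.
    """

    seed: int = 0
    n_genes: int = 1000
    mean_gene_length: int = 900
    intergenic_fraction: float = 0.10
    n_insertions: int = 120_000
    essential_gene_fraction: float = 0.05
    n_essential_clusters: int = 2
    n_sensitive_genes: int = 20
    true_w_treatment: float = 0.5
    true_w_control: float = 1.0
    n_periods: int = 3
    d_per_period: float = 8.0
    read_depth: int = 5_000_000
    n_replicates: int = 2
    library_cells: float = 1.2e9
    bottleneck_cells: float | None = None
    replicon: str = "chromosome"
    #: explicit sensitive gene ids; overrides the random draw
    sensitive_gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_insertions <= 0 or self.read_depth <= 0 or self.n_replicates < 1:
            raise ValueError("counts must be positive")
        for frac in (self.intergenic_fraction, self.essential_gene_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.true_w_treatment < 0 or self.true_w_control < 0:
            raise ValueError("true fitness must be >= 0")
        if self.d_per_period <= 1:
            raise ValueError("d_per_period must exceed 1")


@dataclass
class SimulatedScreen:
    """A complete simulated screen plus its ground truth."""

    config: SimConfig
    dataset: ScreenDataset
    #: one row per site: replicon, position, strand, gene_id, w_control, w_treatment
    truth: pd.DataFrame
    #: one row per gene: gene_id, label in {neutral, sensitive, essential}
    gene_truth: pd.DataFrame

    @property
    def sensitive_genes(self) -> frozenset[str]:
        gt = self.gene_truth
        return frozenset(gt.loc[gt["label"] == "sensitive", "gene_id"])

    def to_directory(self, out_dir: str | Path) -> Path:
        """Write count tables, viable counts, GFF3, truth and a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = []
        for s in self.dataset.samples:
            fname = f"{s.sample_id}.tsv"
            write_count_table(s, out / fname)
            entries.append(
                {
                    "path": fname,
                    "sample_id": s.sample_id,
                    "condition": s.condition,
                    "growth_period": s.growth_period,
                    "replicate": s.replicate,
                }
            )
        write_viable_counts(self.dataset.growth_records, out / "viable_counts.tsv")
        write_gff3(
            self.dataset.annotation,
            out / "genome.gff3",
            {self.config.replicon: self.dataset.genome_length},
        )
        self.truth.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        self.gene_truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        manifest = {
            "annotation": "genome.gff3",
            "genome_length": int(self.dataset.genome_length),
            "viable_counts": "viable_counts.tsv",
            "samples": entries,
        }
        with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        return out / "manifest.yaml"


# ---------------------------------------------------------------------------
# genome and library
# ---------------------------------------------------------------------------


def simulate_genome(config: SimConfig) -> tuple[list[GeneFeature], int, list[str]]:
    """Non-overlapping genes on one replicon, essential genes clustered.

    Gene lengths are normal around ``mean_gene_length`` (sd = mean/4,
    floored at 150 bp); intergenic space is split among the gaps so the
    genome-wide intergenic fraction matches the config.  Essential genes
    are ``n_essential_clusters`` contiguous runs placed at fixed fractions
    of the gene order, mimicking the clustered coverage gaps of real
    genomes.

    Returns ``(features, genome_length, essential_gene_ids)``.
    """
    rng = _rng(config.seed, "genome")
    n = config.n_genes
    lengths = np.maximum(
        150, np.round(rng.normal(config.mean_gene_length, config.mean_gene_length / 4, n))
    ).astype(int)
    total_genic = int(lengths.sum())
    f = config.intergenic_fraction
    total_ig = int(round(total_genic * f / (1 - f))) if f < 1 else 0
    gaps = rng.multinomial(total_ig, np.full(n + 1, 1.0 / (n + 1)))
    strands = rng.choice(["+", "-"], size=n)

    feats = []
    cursor = 1 + int(gaps[0])
    for i in range(n):
        gid = f"gene_{i + 1:04d}"
        feats.append(
            GeneFeature(
                gene_id=gid,
                name=gid,
                replicon=config.replicon,
                start=cursor,
                end=cursor + int(lengths[i]) - 1,
                strand=str(strands[i]),
            )
        )
        cursor += int(lengths[i]) + int(gaps[i + 1])
    genome_length = cursor - 1

    n_ess = int(round(config.essential_gene_fraction * n))
    essential: list[str] = []
    if n_ess:
        k = max(1, min(config.n_essential_clusters, n_ess))
        sizes = [n_ess // k + (1 if j < n_ess % k else 0) for j in range(k)]
        for j, size in enumerate(sizes):
            start_idx = int((j + 1) * n / (k + 1))
            essential.extend(f.gene_id for f in feats[start_idx : start_idx + size])
    if len(set(f.gene_id for f in feats)) + total_ig < n:  # pragma: no cover
        raise ValueError("infeasible genome packing")
    return feats, genome_length, essential


def simulate_library(
    annotation: Sequence[GeneFeature],
    genome_length: int,
    config: SimConfig,
    essential_genes: Sequence[str],
) -> tuple[pd.MultiIndex, np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Insertion sites, equal initial abundances and the truth table.

    Positions are uniform over the genome excluding essential gene bodies;
    sites inside sensitive genes carry the configured treatment fitness.

    Returns ``(site_index, abundances, truth, gene_truth)``.
    """
    rng = _rng(config.seed, "sites")
    essential_set = set(essential_genes)
    allowed = np.ones(genome_length + 1, dtype=bool)
    allowed[0] = False
    for g in annotation:
        if g.gene_id in essential_set:
            allowed[g.start : g.end + 1] = False
    pool = np.flatnonzero(allowed)
    if len(pool) < config.n_insertions:
        raise ValueError(
            f"genome too small: {len(pool)} permissive positions < "
            f"{config.n_insertions} requested insertions"
        )
    positions = np.sort(rng.choice(pool, size=config.n_insertions, replace=False))
    strands = rng.choice(["+", "-"], size=config.n_insertions)
    index = pd.MultiIndex.from_arrays(
        [np.repeat(config.replicon, config.n_insertions), positions, strands],
        names=SITE_INDEX,
    )

    non_essential = [g.gene_id for g in annotation if g.gene_id not in essential_set]
    if config.sensitive_gene_ids is not None:
        sensitive = list(config.sensitive_gene_ids)
        stray = set(sensitive) - set(non_essential)
        if stray:
            raise ValueError(f"sensitive_gene_ids not selectable: {sorted(stray)}")
    else:
        rng_s = _rng(config.seed, "sensitive")
        n_sens = min(config.n_sensitive_genes, len(non_essential))
        sensitive = list(rng_s.choice(non_essential, size=n_sens, replace=False))
    sensitive_set = set(sensitive)

    gene_id = np.full(config.n_insertions, "", dtype=object)
    w_trt = np.ones(config.n_insertions)
    w_ctrl = np.full(config.n_insertions, config.true_w_control)
    for g in annotation:
        inside = (positions >= g.start) & (positions <= g.end)
        gene_id[inside] = g.gene_id
        if g.gene_id in sensitive_set:
            w_trt[inside] = config.true_w_treatment
    truth = pd.DataFrame(
        {
            "replicon": config.replicon,
            "position": positions,
            "strand": strands,
            "gene_id": gene_id,
            "w_control": w_ctrl,
            "w_treatment": w_trt,
        }
    )
    gene_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in annotation],
            "label": [
                "essential"
                if g.gene_id in essential_set
                else ("sensitive" if g.gene_id in sensitive_set else "neutral")
                for g in annotation
            ],
        }
    )
    abundances = np.full(
        config.n_insertions, config.library_cells / config.n_insertions
    )
    return index, abundances, truth, gene_truth


# ---------------------------------------------------------------------------
# growth and sequencing
# ---------------------------------------------------------------------------


def simulate_passage(
    abundances: np.ndarray, w: np.ndarray | float, d: float
) -> tuple[np.ndarray, float, float]:
    """Deterministic exponential growth of every mutant over one period.

    Each mutant's cell count is multiplied by ``d**W``; the realised
    population totals before and after are returned as ``(new_abundances,
    N0, Nf)`` so that the recorded expansion reflects the fitness mixture.
    """
    if d <= 1:
        raise ValueError("d must exceed 1")
    abundances = np.asarray(abundances, dtype=float)
    new = abundances * np.power(float(d), np.asarray(w, dtype=float))
    return new, float(abundances.sum()), float(new.sum())


def sample_reads(
    abundances: np.ndarray,
    depth: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Multinomial sequencing of a culture: ``depth`` reads over sites."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = np.asarray(abundances, dtype=float)
    p = p / p.sum()
    return rng.multinomial(int(depth), p)


def _make_sample(
    index: pd.MultiIndex,
    counts: np.ndarray,
    sample_id: str,
    condition: str,
    growth_period: int,
    replicate: int,
) -> SampleCounts:
    keep = counts > 0
    return SampleCounts(
        sample_id=sample_id,
        condition=condition,
        growth_period=growth_period,
        replicate=replicate,
        counts=pd.Series(counts[keep], index=index[keep]),
    )


def simulate_experiment(
    config: SimConfig, out_dir: str | Path | None = None, screen_tag: int = 0
) -> SimulatedScreen:
    """Run one full simulated screen: library -> starter -> paired arms.

    Produces sequencing samples at every timepoint (library, starter, end
    of each growth period per condition, ``n_replicates`` independent
    multinomial draws each), viable-count records per condition and
    period, the genome annotation and the truth tables.  Byte-deterministic
    under the config seed.  ``screen_tag`` decorrelates the sequencing
    noise of screens sharing one library (multi-screen designs).
    """
    annotation, genome_length, essential = simulate_genome(config)
    index, ab0, truth, gene_truth = simulate_library(
        annotation, genome_length, config, essential
    )
    seed, depth, reps = config.seed, config.read_depth, config.n_replicates
    samples: list[SampleCounts] = []
    growth_records: list[GrowthRecord] = []

    for r in range(1, reps + 1):
        counts = sample_reads(ab0, depth, _rng(seed, "screen", screen_tag, "library", r))
        samples.append(_make_sample(index, counts, f"library_r{r}", "both", 0, r))

    # starter outgrowth: neutral growth of the shared inoculum
    ab_starter, _, _ = simulate_passage(ab0, truth["w_control"].values, config.d_per_period)
    for r in range(1, reps + 1):
        counts = sample_reads(
            ab_starter, depth, _rng(seed, "screen", screen_tag, "starter", r)
        )
        samples.append(_make_sample(index, counts, f"starter_r{r}", "both", 1, r))

    for condition in ("control", "treatment"):
        w = truth[f"w_{condition}"].values
        ab = ab_starter
        for p in range(1, config.n_periods + 1):
            ab, n0, nf = simulate_passage(ab, w, config.d_per_period)
            growth_records.append(GrowthRecord(condition, p, 1, n0, nf))
            if config.bottleneck_cells is not None:
                rng_b = _rng(seed, "screen", screen_tag, "bottleneck", condition == "treatment", p)
                ab = rng_b.multinomial(
                    int(config.bottleneck_cells), ab / ab.sum()
                ).astype(float)
            for r in range(1, reps + 1):
                counts = sample_reads(
                    ab, depth, _rng(seed, "screen", screen_tag, condition, p, r)
                )
                samples.append(
                    _make_sample(
                        index, counts, f"{condition}_t{p + 1}_r{r}", condition, p + 1, r
                    )
                )

    dataset = ScreenDataset(
        samples=samples,
        growth_records=growth_records,
        annotation=annotation,
        genome_length=genome_length,
    )
    screen = SimulatedScreen(
        config=config, dataset=dataset, truth=truth, gene_truth=gene_truth
    )
    if out_dir is not None:
        screen.to_directory(out_dir)
    return screen


def simulate_multi_screen(
    config: SimConfig,
    n_screens: int = 3,
    n_shared: int = 15,
    n_private: int = 5,
) -> list[SimulatedScreen]:
    """Several screens over one library, as with different damaging agents.

    All screens share the genome, insertion library and control arm design;
    each screen's treatment hits ``n_shared`` genes common to every screen
    plus ``n_private`` genes of its own.  Sequencing noise is independent
    across screens.
    """
    annotation, _, essential = simulate_genome(config)
    non_essential = [g.gene_id for g in annotation if g.gene_id not in set(essential)]
    rng = _rng(config.seed, "sensitive")
    needed = n_shared + n_private * n_screens
    chosen = list(rng.choice(non_essential, size=needed, replace=False))
    shared = chosen[:n_shared]
    screens = []
    for k in range(n_screens):
        private = chosen[n_shared + k * n_private : n_shared + (k + 1) * n_private]
        cfg_k = replace(
            config,
            sensitive_gene_ids=tuple(shared + private),
            n_sensitive_genes=len(shared) + len(private),
        )
        screens.append(simulate_experiment(cfg_k, screen_tag=k + 1))
    return screens


# ---------------------------------------------------------------------------
# null proteomics matrix
# ---------------------------------------------------------------------------


def simulate_null_spectral_matrix(
    n_proteins: int = 2000,
    n_replicates: int = 3,
    seed: int = 0,
    mean_log10: float = 1.5,
    sd_log10: float = 0.5,
    noise_cv: float = 0.2,
) -> pd.DataFrame:
    """Exchangeable spectral-count matrix with no true group difference.

    Protein abundances are log-normal across proteins; replicate counts in
    both groups are drawn from the same per-protein distribution
    (multiplicative normal noise with coefficient of variation
    ``noise_cv``), so every rejection of the no-difference null is a false
    positive.  Columns are ``wt_1..wt_n`` and ``dm_1..dm_n``.
    """
    rng = _rng(seed, "spectral")
    base = 10 ** rng.normal(mean_log10, sd_log10, n_proteins)
    cols = {}
    for grp in ("wt", "dm"):
        for r in range(1, n_replicates + 1):
            noise = rng.normal(1.0, noise_cv, n_proteins)
            cols[f"{grp}_{r}"] = np.maximum(base * noise, 0.0)
    df = pd.DataFrame(cols, index=[f"prot_{i + 1:04d}" for i in range(n_proteins)])
    df.index.name = "protein_id"
    return df
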