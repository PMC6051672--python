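"""Quality-control diagnostics for a Tn-seq screen.

Three checks mirror the standard sanity plots for insertion libraries:
coverage along the genome (essential regions show as gaps), the roughly
log-normal distribution of per-site read counts, and the distribution of
per-insertion relative fitness, which should be approximately normal and
centred near 1 when most insertions are neutral to the treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleCounts

__all__ = [
    "coverage_profile",
    "log_count_distribution",
    "relative_fitness_distribution",
    "plot_coverage_profile",
    "plot_histogram",
]


def coverage_profile(
    sample: SampleCounts,
    bin_size: int = 10_000,
    genome_length: int | None = None,
    low_coverage_fraction: float = 0.1,
    replicon: str | None = None,
) -> pd.DataFrame:
    """Summed read coverage in fixed genome bins, on a log10 scale.

    Bins of ``bin_size`` bp tile the replicon from position 1 to
    ``genome_length`` (default: the largest observed insertion position).
    Each bin reports ``log10(sum_reads + 1)``; bins whose raw coverage falls
    below ``low_coverage_fraction`` times the median bin coverage are
    flagged as candidate essential clusters.

    Returns a DataFrame with columns ``replicon, bin_start, bin_end, reads,
    log10_coverage, low_coverage``.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    counts = sample.counts
    if replicon is None:
        reps = counts.index.get_level_values("replicon").unique()
        if len(reps) > 1:
            raise ValueError("multiple replicons present; pass replicon=")
        replicon = reps[0] if len(reps) else "chromosome"
    sub = counts[counts.index.get_level_values("replicon") == replicon]
    pos = sub.index.get_level_values("position").to_numpy()
    vals = sub.to_numpy()
    if genome_length is None:
        genome_length = int(pos.max()) if len(pos) else bin_size
    n_bins = int(np.ceil(genome_length / bin_size))
    reads = np.zeros(n_bins)
    if len(pos):
        bins = np.minimum((pos - 1) // bin_size, n_bins - 1)
        np.add.at(reads, bins, vals)
    starts = np.arange(n_bins) * bin_size + 1
    med = np.median(reads)
    low = reads < low_coverage_fraction * med if med > 0 else reads == 0
    return pd.DataFrame(
        {
            "replicon": replicon,
            "bin_start": starts,
            "bin_end": np.minimum(starts + bin_size - 1, genome_length),
            "reads": reads.astype(int),
            "log10_coverage": np.log10(reads + 1.0),
            "low_coverage": low,
        }
    )


@dataclass
class Histogram:
    """Histogram data plus the summary statistics reported alongside it."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n: int
    mean: float
    sd: float
    skewness: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def _histogram(values: np.ndarray, bin_width: float) -> Histogram:
    if values.size == 0:
        return Histogram(np.array([0.0, bin_width]), np.array([0]), 0, np.nan, np.nan, np.nan)
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    skew = float(stats.skew(values)) if sd > 0 else 0.0
    return Histogram(edges, counts, int(values.size), float(values.mean()), sd, skew)


def log_count_distribution(
    sample: SampleCounts, min_reads: int = 0, bin_width: float = 0.1
) -> Histogram:
    """Distribution of log10(reads) over sites with reads > ``min_reads``.

    The absolute skewness of the log counts is the log-normality
    diagnostic: an approximately log-normal library has |skewness| near 0.
    """
    vals = sample.counts[sample.counts > min_reads].to_numpy()
    if vals.size == 0:
        raise ValueError(f"sample {sample.sample_id!r}: no site above {min_reads} reads")
    return _histogram(np.log10(vals.astype(float)), bin_width)


def relative_fitness_distribution(
    rel_fitness: pd.DataFrame, growth_period: int, bin_width: float = 0.05
) -> Histogram:
    """Distribution of per-insertion relative fitness for one growth period.

    For a screen in which most insertions are neutral to the treatment the
    distribution should be approximately normal with mean close to 1.
    """
    sub = rel_fitness[
        (rel_fitness["growth_period"] == growth_period)
        & ~rel_fitness["excluded"]
        & rel_fitness["w_rel"].notna()
    ]
    if sub.empty:
        raise ValueError(f"no relative-fitness rows for growth period {growth_period}")
    return _histogram(sub["w_rel"].to_numpy(dtype=float), bin_width)


# ---------------------------------------------------------------------------
# plotting hooks
# ---------------------------------------------------------------------------


def plot_coverage_profile(profile: pd.DataFrame, ax=None):
    """Coverage-vs-position plot; flagged low-coverage bins marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    ax.plot(profile["bin_start"], profile["log10_coverage"], lw=0.8, color="C0")
    low = profile[profile["low_coverage"]]
    if len(low):
        ax.plot(low["bin_start"], low["log10_coverage"], "v", color="C3", ms=4)
    ax.set_xlabel("genomic position (nt)")
    ax.set_ylabel("log10 insertion coverage")
    return ax


def plot_histogram(hist: Histogram, ax=None, vline: float | None = None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    widths = np.diff(hist.bin_edges)
    ax.bar(hist.bin_edges[:-1], hist.counts, width=widths, align="edge", color="C0")
    if vline is not None:
        ax.axvline(vline, ls=":", color="k")
    ax.set_ylabel("frequency")
    return ax
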