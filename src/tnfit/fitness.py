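"""Per-insertion fitness from serial-passage frequency change.

The model: a pooled mutant library expands by a known factor ``d = Nf/N0``
(measured by viable-cell counts) over one growth period.  A mutant whose
insertion frequency moves from ``F0`` to ``Ff`` over that expansion has
fitness

    W = ln(Ff * d / F0) / ln((1 - Ff) * d / (1 - F0))

i.e. the mutant's own log expansion relative to the log expansion of the
rest of the population.  ``W = 1`` means the mutant grew exactly with the
population (``Ff = F0``), ``W = 0`` means its absolute abundance did not
change (pure dilution), and extinction (``Ff = 0``) is assigned ``W = 0``
with an ``extinct`` flag rather than a pseudocount.

Treatment effects are isolated by the ratio ``w_rel = W_treatment /
W_control`` computed per insertion per growth period.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .io import SITE_INDEX, SampleCounts, ScreenDataset

logger = logging.getLogger(__name__)

__all__ = [
    "compute_generations",
    "insertion_frequency",
    "insertion_fitness",
    "insertion_fitness_vec",
    "relative_fitness",
    "filter_insertions",
    "pooled_frequencies",
    "fitness_per_period",
]


def compute_generations(N0: float, Nf: float) -> tuple[float, float]:
    """Population generations G = log2(Nf/N0) and expansion factor d = Nf/N0.

    Returns ``(G, d)``. Raises ``ValueError`` for non-positive counts.
    """
    if N0 <= 0 or Nf <= 0:
        raise ValueError(f"viable counts must be positive (N0={N0}, Nf={Nf})")
    d = Nf / N0
    return float(np.log2(d)), float(d)


def insertion_frequency(sample: SampleCounts, site: tuple) -> float:
    """Frequency of one insertion site in a sample; absent site -> 0."""
    total = sample.total_reads
    if total <= 0:
        raise ValueError(f"sample {sample.sample_id!r} has no reads")
    try:
        reads = int(sample.counts.loc[site])
    except KeyError:
        return 0.0
    f = reads / total
    if f >= 1.0:
        logger.warning(
            "site %s carries all reads of sample %s; the rare-mutant "
            "assumption of the fitness model is violated",
            site,
            sample.sample_id,
        )
    return f


def insertion_fitness(
    F0: float, Ff: float, d: float, pseudo_f: float = 0.0
) -> tuple[float, bool]:
    """Fitness W of one insertion over one growth period.

    Parameters
    ----------
    F0, Ff : start / end insertion frequency in [0, 1).
    d : population expansion factor (Nf/N0), must exceed 1.
    pseudo_f : optional frequency pseudocount added to both F0 and Ff
        (sensitivity analysis only; default 0 keeps the extinction convention).

    Returns ``(W, extinct)``.  ``Ff == F0`` returns exactly 1; ``Ff == 0``
    returns 0 with the extinct flag.
    """
    if d <= 1:
        raise ValueError(f"expansion factor d={d} <= 1: fitness undefined")
    if pseudo_f:
        F0, Ff = F0 + pseudo_f, Ff + pseudo_f
    if F0 <= 0:
        raise ValueError("F0 = 0: site absent from the start sample")
    if not (F0 < 1 and 0 <= Ff < 1):
        raise ValueError(f"frequencies must lie in [0, 1) (F0={F0}, Ff={Ff})")
    if Ff == 0:
        return 0.0, True
    if Ff == F0:
        return 1.0, False
    w = np.log(Ff * d / F0) / np.log((1.0 - Ff) * d / (1.0 - F0))
    return float(w), False


def insertion_fitness_vec(
    F0: np.ndarray, Ff: np.ndarray, d: float, floor_at_zero: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`insertion_fitness` over aligned frequency arrays.

    Entries with ``F0 == 0`` yield NaN (no information about the start
    population); extinct entries (``Ff == 0``) yield 0.  Estimates below 0 —
    possible under sampling noise when a frequency drops faster than ``1/d``
    — are floored at 0 unless ``floor_at_zero`` is False.

    Returns ``(W, extinct_mask)``.
    """
    if d <= 1:
        raise ValueError(f"expansion factor d={d} <= 1: fitness undefined")
    F0 = np.asarray(F0, dtype=float)
    Ff = np.asarray(Ff, dtype=float)
    valid = F0 > 0
    extinct = valid & (Ff == 0)
    w = np.full(F0.shape, np.nan)
    calc = valid & ~extinct
    with np.errstate(divide="ignore", invalid="ignore"):
        w[calc] = np.log(Ff[calc] * d / F0[calc]) / np.log(
            (1.0 - Ff[calc]) * d / (1.0 - F0[calc])
        )
    w[valid & (Ff == F0)] = 1.0  # exact neutrality, no rounding wobble
    w[extinct] = 0.0
    if floor_at_zero:
        w[calc & (w < 0)] = 0.0
    return w, extinct


def relative_fitness(W_treatment: float, W_control: float) -> float:
    """Treatment/control fitness ratio for one insertion.

    A control-extinct mutant (``W_control <= 0``) carries no information
    about the treatment; callers must exclude such sites (raised here).
    """
    if W_control <= 0:
        raise ValueError(
            f"W_control={W_control} <= 0: control-extinct site carries no "
            "information about the treatment"
        )
    return W_treatment / W_control


def filter_insertions(
    control_sample: SampleCounts | pd.Series, threshold: int = 10
) -> pd.MultiIndex:
    """Sites with strictly more than ``threshold`` reads in the control sample.

    The screen's read filter: applied per growth period to that period's
    control start sample (replicates summed).
    """
    counts = (
        control_sample.counts
        if isinstance(control_sample, SampleCounts)
        else control_sample
    )
    kept = counts[counts > threshold]
    return kept.index


def pooled_frequencies(samples: Iterable[SampleCounts]) -> pd.Series:
    """Replicate-averaged site frequencies for one (condition, timepoint).

    Each replicate is converted to frequencies first, then frequencies are
    averaged across replicates (a site absent from a replicate contributes 0).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples to pool")
    freqs = [s.frequencies() for s in samples]
    df = pd.concat(freqs, axis=1).fillna(0.0)
    return df.mean(axis=1)


def summed_counts(samples: Iterable[SampleCounts]) -> pd.Series:
    """Replicate-summed raw counts for one (condition, timepoint)."""
    samples = list(samples)
    if not samples:
        raise ValueError("no samples to sum")
    df = pd.concat([s.counts for s in samples], axis=1).fillna(0)
    return df.sum(axis=1).astype("int64")


def _geomean_d(records) -> float:
    ds = [g.d for g in records]
    if not ds:
        raise ValueError("no growth record")
    return float(np.exp(np.mean(np.log(ds))))


def fitness_per_period(
    dataset: ScreenDataset,
    min_control_reads: int = 10,
    periods: Iterable[int] | None = None,
    pool_replicates: bool = True,
    pseudocount: float = 0.0,
    floor_at_zero: bool = True,
) -> pd.DataFrame:
    """Per-insertion fitness and treatment/control relative fitness.

    For each growth period ``p`` (1..3 by default), ``F0`` is taken from the
    sample at timepoint ``p`` and ``Ff`` from timepoint ``p + 1`` for each
    condition; the expansion factor ``d`` is the geometric mean over that
    condition/period's viable-count records.  Sites must pass the control
    read filter (strictly more than ``min_control_reads`` reads, replicates
    summed) on the period's control start sample.

    When ``pool_replicates`` is True (default) replicate frequencies are
    averaged before W is computed; otherwise replicate pairs are matched by
    replicate number and per-pair ratios are averaged.

    Returns a tidy DataFrame with one row per (site, period) and columns
    ``F0_control, Ff_control, F0_treatment, Ff_treatment, d_control,
    d_treatment, W_control, W_treatment, w_rel, extinct_control,
    extinct_treatment, excluded, exclusion_reason``.
    """
    if periods is None:
        periods = (1, 2, 3)
    out_frames = []
    for p in periods:
        start_tp, end_tp = p, p + 1
        ctrl_start = dataset.get_samples(start_tp, "control")
        ctrl_end = dataset.get_samples(end_tp, "control")
        trt_start = dataset.get_samples(start_tp, "treatment")
        trt_end = dataset.get_samples(end_tp, "treatment")
        g_ctrl = dataset.get_growth(p, "control")
        g_trt = dataset.get_growth(p, "treatment")
        if not (ctrl_start and ctrl_end and trt_start and trt_end and g_ctrl and g_trt):
            logger.warning(
                "growth period %d skipped: missing samples or viable counts", p
            )
            continue
        kept = filter_insertions(summed_counts(ctrl_start), min_control_reads)
        d_c, d_t = _geomean_d(g_ctrl), _geomean_d(g_trt)

        if pool_replicates:
            block = _period_block(
                kept,
                pooled_frequencies(ctrl_start),
                pooled_frequencies(ctrl_end),
                pooled_frequencies(trt_start),
                pooled_frequencies(trt_end),
                d_c,
                d_t,
                pseudocount,
                floor_at_zero,
            )
        else:
            reps = sorted(
                {s.replicate for s in ctrl_start}
                & {s.replicate for s in ctrl_end}
                & {s.replicate for s in trt_start}
                & {s.replicate for s in trt_end}
            )
            if not reps:
                logger.warning("period %d skipped: no matched replicate sets", p)
                continue
            per_rep = []
            for r in reps:
                sel = lambda ss: [s for s in ss if s.replicate == r]  # noqa: E731
                per_rep.append(
                    _period_block(
                        kept,
                        pooled_frequencies(sel(ctrl_start)),
                        pooled_frequencies(sel(ctrl_end)),
                        pooled_frequencies(sel(trt_start)),
                        pooled_frequencies(sel(trt_end)),
                        d_c,
                        d_t,
                        pseudocount,
                        floor_at_zero,
                    )
                )
            block = per_rep[0].copy()
            wrels = pd.concat([b["w_rel"] for b in per_rep], axis=1)
            block["w_rel"] = wrels.mean(axis=1).values
            block["excluded"] = np.any([b["excluded"] for b in per_rep], axis=0)
        block.insert(0, "growth_period", p)
        out_frames.append(block.reset_index())
    if not out_frames:
        return pd.DataFrame(
            columns=["growth_period"]
            + SITE_INDEX
            + [
                "F0_control",
                "Ff_control",
                "F0_treatment",
                "Ff_treatment",
                "d_control",
                "d_treatment",
                "W_control",
                "W_treatment",
                "w_rel",
                "extinct_control",
                "extinct_treatment",
                "excluded",
                "exclusion_reason",
            ]
        )
    return pd.concat(out_frames, ignore_index=True)


def _period_block(
    kept: pd.MultiIndex,
    f0_c: pd.Series,
    ff_c: pd.Series,
    f0_t: pd.Series,
    ff_t: pd.Series,
    d_c: float,
    d_t: float,
    pseudocount: float,
    floor_at_zero: bool,
) -> pd.DataFrame:
    idx = kept.sortlevel()[0]

    def _on(f: pd.Series) -> np.ndarray:
        v = f.reindex(idx).fillna(0.0).values + pseudocount
        return v

    F0c, Ffc, F0t, Fft = _on(f0_c), _on(ff_c), _on(f0_t), _on(ff_t)
    Wc, ext_c = insertion_fitness_vec(F0c, Ffc, d_c, floor_at_zero)
    Wt, ext_t = insertion_fitness_vec(F0t, Fft, d_t, floor_at_zero)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_rel = np.where(Wc > 0, Wt / Wc, np.nan)
    reason = np.full(len(idx), "", dtype=object)
    reason[np.isnan(Wt)] = "missing_treatment_start"
    reason[np.isnan(Wc)] = "missing_control_start"
    reason[(~np.isnan(Wc)) & (Wc <= 0)] = "control_nonpositive_fitness"
    excluded = reason != ""
    return pd.DataFrame(
        {
            "F0_control": F0c,
            "Ff_control": Ffc,
            "F0_treatment": F0t,
            "Ff_treatment": Fft,
            "d_control": d_c,
            "d_treatment": d_t,
            "W_control": Wc,
            "W_treatment": Wt,
            "w_rel": w_rel,
            "extinct_control": ext_c,
            "extinct_treatment": ext_t,
            "excluded": excluded,
            "exclusion_reason": reason,
        },
        index=idx,
    )
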