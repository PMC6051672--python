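"""Model/Results interface over the Tn-seq screen pipeline.

:class:`TnseqScreen` holds the data of one screen (count samples, viable
counts, annotation) and the fitting options; :meth:`TnseqScreen.fit`
estimates per-insertion fitness and gene-level relative fitness and
returns a :class:`TnseqScreenResults` carrying the estimate tables, their
confidence intervals and p-values, candidate selection, QC diagnostics
and a text summary — the same division of labour as a statsmodels model
and its results object.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from . import qc as _qc
from .fitness import fitness_per_period
from .genes import gene_fitness_table, select_candidates
from .io import GeneFeature, ScreenDataset, read_manifest, write_gene_table
from .simulate import SimConfig, SimulatedScreen, simulate_experiment

__all__ = ["TnseqScreen", "TnseqScreenResults"]


class TnseqScreen:
    """A serial-passage Tn-seq fitness screen to be fitted.

    Parameters
    ----------
    dataset : the screen's count samples, viable-cell records and (optional)
        gene annotation.
    experiment_id : label used in summaries and overlap comparisons.
    """

    def __init__(self, dataset: ScreenDataset, experiment_id: str = "screen") -> None:
        self.dataset = dataset
        self.experiment_id = experiment_id

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_manifest(
        cls, path: str | Path, experiment_id: str | None = None, **kwargs
    ) -> "TnseqScreen":
        """Build a screen from a run-manifest YAML (see :func:`tnfit.io.read_manifest`)."""
        ds = read_manifest(path, **kwargs)
        return cls(ds, experiment_id or Path(path).parent.name or "screen")

    @classmethod
    def from_simulation(
        cls, config: SimConfig | SimulatedScreen | None = None, experiment_id: str = "sim"
    ) -> "TnseqScreen":
        """Build a screen from a synthetic experiment (default config if None).

        The simulated truth is kept on the model as ``.truth`` /
        ``.gene_truth`` for recovery checks.
        """
        if config is None:
            config = SimConfig()
        sim = config if isinstance(config, SimulatedScreen) else simulate_experiment(config)
        model = cls(sim.dataset, experiment_id)
        model.truth = sim.truth
        model.gene_truth = sim.gene_truth
        return model

    # -- estimation --------------------------------------------------------

    def fit(
        self,
        min_control_reads: int = 10,
        min_insertions: int = 3,
        periods: Iterable[int] | None = None,
        pool_replicates: bool = True,
        pseudocount: float = 0.0,
        include_intergenic: bool = True,
    ) -> "TnseqScreenResults":
        """Estimate per-insertion and per-gene relative fitness.

        ``min_control_reads`` is the per-period control read filter
        (strictly greater than), ``min_insertions`` the "sufficient data"
        threshold for a gene-level estimate.
        """
        rel = fitness_per_period(
            self.dataset,
            min_control_reads=min_control_reads,
            periods=periods,
            pool_replicates=pool_replicates,
            pseudocount=pseudocount,
        )
        genes = (
            gene_fitness_table(
                rel,
                self.dataset.annotation,
                min_insertions=min_insertions,
                include_intergenic=include_intergenic,
            )
            if self.dataset.annotation
            else pd.DataFrame()
        )
        return TnseqScreenResults(self, rel, genes)


class TnseqScreenResults:
    """Fitted screen: estimate tables, candidate selection, QC, summary."""

    def __init__(
        self,
        model: TnseqScreen,
        insertion_fitness: pd.DataFrame,
        gene_fitness: pd.DataFrame,
    ) -> None:
        self.model = model
        #: per-(site, period) table: F0/Ff per condition, d, W, w_rel, flags
        self.insertion_fitness = insertion_fitness
        #: per-(gene, period) table: n, mean w_rel, 95% CI, p, BH-adjusted p
        self.gene_fitness = gene_fitness

    # -- selection ---------------------------------------------------------

    def candidates(
        self, growth_period: int = 2, top_n: int = 200, alpha: float = 0.01
    ) -> pd.DataFrame:
        """Lowest-fitness genes with adjusted p below ``alpha`` (ranked)."""
        return select_candidates(self.gene_fitness, growth_period, top_n, alpha)

    def gene(self, gene_id: str) -> pd.DataFrame:
        """All periods' estimates for one gene."""
        return self.gene_fitness[self.gene_fitness["gene_id"] == gene_id]

    # -- QC ----------------------------------------------------------------

    def relative_fitness_distribution(self, growth_period: int, bin_width: float = 0.05):
        return _qc.relative_fitness_distribution(
            self.insertion_fitness, growth_period, bin_width
        )

    # -- output ------------------------------------------------------------

    def save_gene_table(self, path: str | Path) -> None:
        write_gene_table(self.gene_fitness, path)

    def summary(self, growth_period: int = 2, top: int = 10) -> str:
        """Human-readable summary of the fitted screen."""
        rel = self.insertion_fitness
        lines = [
            f"Tn-seq screen results: {self.model.experiment_id}",
            "=" * 58,
        ]
        for p, grp in rel.groupby("growth_period"):
            ok = grp[~grp["excluded"]]
            lines.append(
                f"period {p}: {len(grp):>7d} sites passing read filter, "
                f"{len(ok):>7d} with w_rel "
                f"(mean {ok['w_rel'].mean():.3f}, sd {ok['w_rel'].std():.3f})"
            )
        if len(self.gene_fitness):
            gsub = self.gene_fitness[
                self.gene_fitness["growth_period"] == growth_period
            ]
            n_sig = int((gsub["p_adj"] < 0.01).sum())
            lines.append(
                f"genes with sufficient data in period {growth_period}: "
                f"{len(gsub)} ({n_sig} with adjusted p < 0.01)"
            )
            cand = self.candidates(growth_period, top_n=top)
            if len(cand):
                lines.append("")
                lines.append(
                    f"top {len(cand)} candidates, period {growth_period} "
                    "(mean w_rel [95% CI], adjusted p):"
                )
                for row in cand.itertuples(index=False):
                    lines.append(
                        f"  {row.gene_id:<12s} {row.mean_relative_fitness:6.3f} "
                        f"[{row.ci95_low:6.3f}, {row.ci95_high:6.3f}]  "
                        f"p_adj={row.p_adj:.2e}  n={row.n_insertions}"
                    )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<TnseqScreenResults {self.model.experiment_id!r}: "
            f"{len(self.insertion_fitness)} site-period rows, "
            f"{len(self.gene_fitness)} gene-period rows>"
        )
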