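"""Readers and writers for every external table the screen pipeline touches.

All tables are UTF-8 TSV with ``#``-prefixed comment lines; genome coordinates
are 1-based inclusive (GFF3 convention) throughout, and an insertion position
is a single base coordinate.

Sampling timepoints are encoded in :attr:`SampleCounts.growth_period`:
``0`` = initial transposon library, ``1`` = starter culture (the shared
inoculum from which control and treatment arms are split), and ``2..4`` =
the sample taken at the end of growth periods 1..3 of one arm.  A growth
*period* ``p`` therefore spans timepoints ``p`` (start) to ``p + 1`` (end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SITE_INDEX = ["replicon", "position", "strand"]

#: conditions legal for post-split samples
CONDITIONS = ("control", "treatment")
#: "both" marks pre-split samples (library / starter), shared by the two arms
CONDITIONS_EXTENDED = CONDITIONS + ("both",)

GENE_TABLE_COLUMNS = [
    "gene_id",
    "growth_period",
    "n_insertions",
    "mean_relative_fitness",
    "ci95_low",
    "ci95_high",
    "p_value",
    "p_adj",
]


class SchemaError(ValueError):
    """A table violated its documented schema or an invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene (or CDS) on a replicon, 1-based inclusive."""

    gene_id: str
    name: str
    replicon: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise SchemaError(
                f"gene {self.gene_id!r}: coordinates must be positive "
                f"(got {self.start}..{self.end})"
            )
        if self.end < self.start:
            raise SchemaError(
                f"gene {self.gene_id!r}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise SchemaError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SampleCounts:
    """Per-site read counts for one sequencing sample.

    ``counts`` is a :class:`pandas.Series` of non-negative integers indexed by
    ``(replicon, position, strand)``.
    """

    sample_id: str
    condition: str
    growth_period: int
    replicate: int
    counts: pd.Series

    def __post_init__(self) -> None:
        if self.growth_period not in (0, 1, 2, 3, 4):
            raise SchemaError(
                f"sample {self.sample_id!r}: growth_period must be in 0..4 "
                f"(0=library, 1=starter, 2-4=end of periods 1-3)"
            )
        legal = CONDITIONS_EXTENDED if self.growth_period <= 1 else CONDITIONS
        if self.condition not in legal:
            raise SchemaError(
                f"sample {self.sample_id!r}: condition {self.condition!r} "
                f"not in {legal} for growth_period {self.growth_period}"
            )
        if self.replicate < 1:
            raise SchemaError(f"sample {self.sample_id!r}: replicate must be >= 1")
        c = self.counts
        if not isinstance(c, pd.Series):
            c = pd.Series(dict(c), dtype="int64")
            c.index = pd.MultiIndex.from_tuples(c.index, names=SITE_INDEX)
            self.counts = c
        if c.index.nlevels != 3:
            raise SchemaError("counts index must be (replicon, position, strand)")
        self.counts.index.names = SITE_INDEX
        if len(c) and (c.values < 0).any():
            raise SchemaError(f"sample {self.sample_id!r}: negative read count")
        if c.index.has_duplicates:
            raise SchemaError(f"sample {self.sample_id!r}: duplicate site rows")
        if len(c):
            pos = c.index.get_level_values("position")
            if (np.asarray(pos) < 1).any():
                raise SchemaError(f"sample {self.sample_id!r}: non-positive position")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def n_sites(self) -> int:
        return int((self.counts > 0).sum())

    def frequencies(self) -> pd.Series:
        """Per-site read frequencies (reads / total_reads)."""
        tot = self.total_reads
        if tot == 0:
            raise SchemaError(f"sample {self.sample_id!r}: no reads")
        return self.counts / tot

    def collapse_strands(self) -> "SampleCounts":
        """Sum the two strands of each (replicon, position) into one '+' site."""
        pooled = self.counts.groupby(level=["replicon", "position"]).sum()
        idx = pd.MultiIndex.from_arrays(
            [
                pooled.index.get_level_values("replicon"),
                pooled.index.get_level_values("position"),
                np.repeat("+", len(pooled)),
            ],
            names=SITE_INDEX,
        )
        return SampleCounts(
            sample_id=self.sample_id,
            condition=self.condition,
            growth_period=self.growth_period,
            replicate=self.replicate,
            counts=pd.Series(pooled.values, index=idx),
        )


@dataclass(frozen=True)
class GrowthRecord:
    """Start/end viable-cell counts for one culture over one growth period."""

    condition: str
    growth_period: int
    replicate: int
    N0: float
    Nf: float

    def __post_init__(self) -> None:
        if self.N0 <= 0 or self.Nf <= 0:
            raise SchemaError(
                f"viable counts must be positive (N0={self.N0}, Nf={self.Nf})"
            )

    @property
    def d(self) -> float:
        """Population expansion factor Nf / N0."""
        return self.Nf / self.N0

    @property
    def generations(self) -> float:
        return float(np.log2(self.d))


@dataclass
class ScreenDataset:
    """All inputs of one Tn-seq screen: count samples, viable counts, genes."""

    samples: list[SampleCounts]
    growth_records: list[GrowthRecord]
    annotation: list[GeneFeature] = field(default_factory=list)
    genome_length: int | None = None

    def get_samples(
        self, growth_period: int, condition: str | None = None
    ) -> list[SampleCounts]:
        """Samples at a timepoint; pre-split 'both' samples match either arm."""
        out = []
        for s in self.samples:
            if s.growth_period != growth_period:
                continue
            if condition is None or s.condition == condition or s.condition == "both":
                out.append(s)
        return out

    def get_growth(self, growth_period: int, condition: str) -> list[GrowthRecord]:
        return [
            g
            for g in self.growth_records
            if g.growth_period == growth_period and g.condition == condition
        ]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(
    path: str | Path, feature_types: Sequence[str] = ("gene", "CDS")
) -> list[GeneFeature]:
    """Read gene features from a GFF3 file.

    One :class:`GeneFeature` is returned per record whose type is in
    ``feature_types`` (a gene with both a ``gene`` and ``CDS`` record is not
    duplicated: the first record per ID wins).  Coordinates are kept 1-based
    inclusive as in the file.
    """
    path = Path(path)
    feats: dict[str, GeneFeature] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise SchemaError(
                    f"{path.name}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(parts)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise SchemaError(
                    f"{path.name}:{lineno}: non-integer coordinates "
                    f"{start_s!r}..{end_s!r}"
                ) from None
            attr_map = {}
            for item in attrs.split(";"):
                item = item.strip()
                if item and "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k] = v
            if "ID" not in attr_map:
                raise SchemaError(f"{path.name}:{lineno}: record has no ID attribute")
            gene_id = attr_map["ID"]
            try:
                feat = GeneFeature(
                    gene_id=gene_id,
                    name=attr_map.get("Name", gene_id),
                    replicon=seqid,
                    start=start,
                    end=end,
                    strand=strand if strand in ("+", "-") else "+",
                )
            except SchemaError as exc:
                raise SchemaError(f"{path.name}:{lineno}: {exc}") from None
            feats.setdefault(gene_id, feat)
    if not feats:
        logger.warning("no %s features found in %s", "/".join(feature_types), path)
    return list(feats.values())


def write_gff3(
    features: Iterable[GeneFeature],
    path: str | Path,
    replicon_lengths: dict[str, int] | None = None,
) -> None:
    """Write features as GFF3 ``gene`` records (deterministic byte output)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        if replicon_lengths:
            for rep, length in sorted(replicon_lengths.items()):
                fh.write(f"##sequence-region {rep} 1 {length}\n")
        for f in features:
            fh.write(
                f"{f.replicon}\ttnfit\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t"
                f"ID={f.gene_id};Name={f.name}\n"
            )


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


def read_count_table(
    path: str | Path,
    sample_id: str | None = None,
    condition: str = "both",
    growth_period: int = 0,
    replicate: int = 1,
    collapse_strands: bool = False,
) -> SampleCounts:
    """Read a per-site read-count TSV (columns replicon, position, strand, count)."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"replicon": str, "position": "int64", "strand": str, "count": "int64"},
    )
    missing = {"replicon", "position", "strand", "count"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing columns {sorted(missing)}")
    counts = pd.Series(
        df["count"].values,
        index=pd.MultiIndex.from_arrays(
            [df["replicon"], df["position"], df["strand"]], names=SITE_INDEX
        ),
    )
    sc = SampleCounts(
        sample_id=sample_id or path.stem,
        condition=condition,
        growth_period=growth_period,
        replicate=replicate,
        counts=counts,
    )
    if collapse_strands:
        sc = sc.collapse_strands()
    return sc


def write_count_table(sample: SampleCounts, path: str | Path) -> None:
    """Write a SampleCounts to TSV, sorted by site for deterministic bytes."""
    df = sample.counts.sort_index().rename("count").reset_index()
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene fitness table
# ---------------------------------------------------------------------------


def write_gene_table(gene_fitness: pd.DataFrame, path: str | Path) -> None:
    """Write the gene-level relative-fitness table.

    Rows are sorted ascending by mean relative fitness (candidate-list
    presentation order).  Records with ``n_insertions == 0`` are refused:
    genes without data must be filtered upstream.
    """
    missing = set(GENE_TABLE_COLUMNS) - set(gene_fitness.columns)
    if missing:
        raise SchemaError(f"gene table missing columns {sorted(missing)}")
    if len(gene_fitness) and (gene_fitness["n_insertions"] < 1).any():
        raise SchemaError("gene table contains records with n_insertions == 0")
    out = gene_fitness.sort_values(
        ["mean_relative_fitness", "p_adj", "gene_id"], kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False, columns=GENE_TABLE_COLUMNS)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{Path(path).name}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# viable counts, cell lengths, spectral counts
# ---------------------------------------------------------------------------


def read_viable_counts(path: str | Path) -> list[GrowthRecord]:
    """Read the viable-cell-count TSV (condition, growth_period, replicate, N0, Nf)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"condition", "growth_period", "replicate", "N0", "Nf"} - set(df.columns)
    if missing:
        raise SchemaError(f"{Path(path).name}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GrowthRecord(
                condition=str(row.condition),
                growth_period=int(row.growth_period),
                replicate=int(row.replicate),
                N0=float(row.N0),
                Nf=float(row.Nf),
            )
        )
    return records


def write_viable_counts(records: Iterable[GrowthRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "condition": g.condition,
                "growth_period": g.growth_period,
                "replicate": g.replicate,
                "N0": g.N0,
                "Nf": g.Nf,
            }
            for g in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_length_table(path: str | Path) -> pd.DataFrame:
    """Read a cell-length TSV (strain, condition, timepoint, length_um)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"strain", "condition", "timepoint", "length_um"} - set(df.columns)
    if missing:
        raise SchemaError(f"{Path(path).name}: missing columns {sorted(missing)}")
    if (df["length_um"] <= 0).any():
        raise SchemaError(f"{Path(path).name}: non-positive cell length")
    return df


def read_spectral_table(path: str | Path) -> pd.DataFrame:
    """Read a spectral-count matrix (protein_id column, one column per sample).

    Every protein must be present in every sample (no missing cells).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "protein_id" not in df.columns:
        raise SchemaError(f"{Path(path).name}: missing protein_id column")
    if df["protein_id"].duplicated().any():
        raise SchemaError(f"{Path(path).name}: duplicate protein rows")
    df = df.set_index("protein_id")
    if df.shape[1] < 1:
        raise SchemaError(f"{Path(path).name}: no sample columns")
    if df.isna().any().any():
        raise SchemaError(
            f"{Path(path).name}: ragged matrix (a sample is missing protein rows)"
        )
    if (df.values < 0).any():
        raise SchemaError(f"{Path(path).name}: negative spectral count")
    return df


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path, collapse_strands: bool = False) -> ScreenDataset:
    """Load a run manifest (YAML) mapping count files to their sample roles.

    Schema::

        annotation: genome.gff3          # optional
        genome_length: 1083000           # optional
        viable_counts: viable_counts.tsv
        samples:
          - {path: starter_r1.tsv, condition: both, growth_period: 1, replicate: 1}
          - {path: ctrl_p1_r1.tsv, condition: control, growth_period: 2, replicate: 1}

    Relative paths resolve against the manifest's directory.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict) or "samples" not in spec:
        raise SchemaError(f"{path.name}: manifest must contain a 'samples' list")
    base = path.parent

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    samples = []
    for entry in spec["samples"]:
        samples.append(
            read_count_table(
                _resolve(entry["path"]),
                sample_id=entry.get("sample_id"),
                condition=entry["condition"],
                growth_period=int(entry["growth_period"]),
                replicate=int(entry.get("replicate", 1)),
                collapse_strands=collapse_strands,
            )
        )
    growth = (
        read_viable_counts(_resolve(spec["viable_counts"]))
        if "viable_counts" in spec
        else []
    )
    annotation = (
        read_gff3(_resolve(spec["annotation"])) if "annotation" in spec else []
    )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise SchemaError(f"{path.name}: duplicate sample_id in manifest")
    return ScreenDataset(
        samples=samples,
        growth_records=growth,
        annotation=annotation,
        genome_length=spec.get("genome_length"),
    )
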