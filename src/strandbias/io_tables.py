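"""Readers and writers for gene tables, annotations, geometry and results.

Coordinates are 1-based inclusive throughout (GenBank/GFF convention); any
half-open arithmetic is internal to the functions that need it. TSV is the
canonical interchange format; GFF3 is supported for reading gene features.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

WATSON = "watson"
CRICK = "crick"

_STRAND_CODES = {"+": WATSON, "-": CRICK, "watson": WATSON, "crick": CRICK}


class TableParseError(ValueError):
    """A tabular input failed to parse or violated an invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene's coordinates and coding strand on a named circular chromosome.

    ``start`` and ``end`` are 1-based inclusive. A gene spanning the
    coordinate origin of the circle has ``start > end`` and must carry
    ``wraps=True``.
    """

    gene_id: str
    chromosome_id: str
    start: int
    end: int
    coding_strand: str
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.coding_strand not in (WATSON, CRICK):
            raise TableParseError(
                f"gene {self.gene_id!r}: coding_strand must be "
                f"'watson' or 'crick', got {self.coding_strand!r}"
            )
        if self.start < 1 or self.end < 1:
            raise TableParseError(
                f"gene {self.gene_id!r}: coordinates are 1-based; "
                f"got start={self.start}, end={self.end}"
            )
        if self.start > self.end and not self.wraps:
            raise TableParseError(
                f"gene {self.gene_id!r}: start > end is only permitted for "
                "genes wrapping the coordinate origin (wraps=True)"
            )

    @property
    def length(self) -> int | None:
        """Gene length in bp; None for wrapped genes (needs chromosome length)."""
        if self.wraps:
            return None
        return self.end - self.start + 1


@dataclass(frozen=True)
class ReplicationGeometry:
    """Chromosome length plus oriC and ter positions defining two replichores."""

    chromosome_id: str
    length: int
    oric_position: int
    ter_position: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"chromosome length must be positive, got {self.length}")
        for name, pos in (("oric_position", self.oric_position),
                          ("ter_position", self.ter_position)):
            if not (1 <= pos <= self.length):
                raise ValueError(
                    f"{name}={pos} outside chromosome [1, {self.length}]"
                )
        if self.oric_position == self.ter_position:
            raise ValueError("oriC and ter positions must differ")


ANNOTATION_COLUMNS = ("fitness", "geptop_score", "essential", "expression")


@dataclass
class AnnotationTable:
    """Per-gene quantitative fitness, binary essentiality and expression level.

    Backed by a DataFrame indexed by gene_id with any subset of the columns
    ``fitness``, ``geptop_score``, ``essential``, ``expression``; missing
    cells are NaN, never silently zero.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "gene_id":
            raise TableParseError("AnnotationTable index must be named 'gene_id'")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise TableParseError(f"duplicate gene_id {dup!r} in annotation table")
        unknown = set(df.columns) - set(ANNOTATION_COLUMNS)
        if unknown:
            raise TableParseError(f"unknown annotation columns: {sorted(unknown)}")
        if "fitness" in df.columns:
            bad = df.index[(df["fitness"] < 0) | (df["fitness"] > 1)]
            if len(bad):
                raise TableParseError(
                    f"fitness outside [0, 1] for gene {bad[0]!r}"
                )
        if "essential" in df.columns:
            ess = df["essential"].dropna()
            if not ess.isin((0, 1)).all():
                bad = ess.index[~ess.isin((0, 1))][0]
                raise TableParseError(
                    f"essential not in {{0, 1}} for gene {bad!r}"
                )
        if "expression" in df.columns:
            bad = df.index[df["expression"] < 0]
            if len(bad):
                raise TableParseError(
                    f"negative expression for gene {bad[0]!r}"
                )

    def column(self, name: str) -> pd.Series:
        """One annotation column restricted to genes where it is present."""
        if name not in self.data.columns:
            return pd.Series(dtype=float, name=name).rename_axis("gene_id")
        return self.data[name].dropna()

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class StrandClassTable:
    """Per-gene leading/lagging classification, also exposed as 0/1 codes."""

    classes: pd.Series  # gene_id -> {"leading", "lagging"}

    def __post_init__(self) -> None:
        if not self.classes.isin(("leading", "lagging")).all():
            raise ValueError("strand classes must be 'leading' or 'lagging'")
        if self.classes.index.has_duplicates:
            raise ValueError("duplicate gene_id in strand class table")
        self.classes = self.classes.rename_axis("gene_id")

    @property
    def binary(self) -> pd.Series:
        """Strand class encoded as leading=1, lagging=0."""
        return (self.classes == "leading").astype(int)

    @property
    def leading_fraction(self) -> float:
        return float(self.binary.mean())

    def __len__(self) -> int:
        return len(self.classes)


def _coerce_coordinate(value, what: str, line: int) -> int:
    try:
        as_float = float(value)
    except (TypeError, ValueError):
        raise TableParseError(f"line {line}: {what}={value!r} is not an integer")
    if as_float != int(as_float):
        raise TableParseError(f"line {line}: {what}={value!r} is not an integer")
    coord = int(as_float)
    if coord < 1:
        raise TableParseError(
            f"line {line}: {what}={coord} out of range (coordinates are 1-based)"
        )
    return coord


def _records_from_frame(df: pd.DataFrame, first_data_line: int) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for offset, row in enumerate(df.itertuples(index=False)):
        line = first_data_line + offset
        gene_id = str(row.gene_id)
        if gene_id in seen:
            raise TableParseError(f"line {line}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        strand = _STRAND_CODES.get(str(row.strand))
        if strand is None:
            logger.warning(
                "line %d: gene %s has no usable strand (%r); skipped",
                line, gene_id, row.strand,
            )
            continue
        start = _coerce_coordinate(row.start, "start", line)
        end = _coerce_coordinate(row.end, "end", line)
        wraps = bool(getattr(row, "wraps", False)) or start > end
        try:
            records.append(
                GeneRecord(gene_id, str(row.chromosome_id), start, end, strand,
                           wraps=wraps)
            )
        except TableParseError as exc:
            raise TableParseError(f"line {line}: {exc}") from exc
    return records


def _read_gene_tsv(path: str) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chromosome_id", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise TableParseError(
            f"{path}: missing required columns {sorted(missing)}"
        )
    if "wraps" in df.columns:
        df["wraps"] = df["wraps"].map(
            lambda v: str(v).strip().lower() in ("1", "true", "yes")
        )
    return _records_from_frame(df, first_data_line=2)


def _gff3_gene_id(feature) -> str | None:
    for key in ("ID", "locus_tag", "Name", "gene_id"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def _read_gene_gff3(path: str) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for feature in db.features_of_type("gene", order_by="start"):
        gene_id = _gff3_gene_id(feature)
        if gene_id is None:
            raise TableParseError(
                f"{path}: gene feature at {feature.start}-{feature.end} lacks an ID"
            )
        if gene_id in seen:
            raise TableParseError(f"{path}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        strand = _STRAND_CODES.get(feature.strand)
        if strand is None:
            logger.warning(
                "%s: gene %s has strand %r; skipped", path, gene_id, feature.strand
            )
            continue
        records.append(
            GeneRecord(gene_id, feature.seqid, feature.start, feature.end, strand)
        )
    return records


def read_gene_table(path: str, format: str = "tsv") -> list[GeneRecord]:
    """Read gene records from a TSV or GFF3 file.

    The TSV dialect has header columns gene_id, chromosome_id, start, end,
    strand (``+``/``-`` or ``watson``/``crick``) and an optional ``wraps``
    column for genes spanning the circle's coordinate origin. Features
    without a strand are skipped with a logged warning; input order is
    preserved for TSV.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_gene_tsv(path)
    if format == "gff3":
        return _read_gene_gff3(path)
    raise ValueError(f"unknown gene table format {format!r}")


def read_annotation_table(path: str) -> AnnotationTable:
    """Read a per-gene annotation TSV (gene_id plus any subset of
    fitness / geptop_score / essential / expression). Empty cells become
    missing values."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise TableParseError(f"{path}: missing gene_id column")
    df["gene_id"] = df["gene_id"].astype(str)
    df = df.set_index("gene_id")
    keep = [c for c in df.columns if c in ANNOTATION_COLUMNS]
    return AnnotationTable(df[keep].astype(float))


def read_geometry(path: str) -> ReplicationGeometry:
    """Read replication geometry from a YAML mapping with keys
    chromosome_id, length, oric_position, ter_position."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise TableParseError(f"{path}: geometry file must be a YAML mapping")
    try:
        return ReplicationGeometry(
            chromosome_id=str(raw["chromosome_id"]),
            length=int(raw["length"]),
            oric_position=int(raw["oric_position"]),
            ter_position=int(raw["ter_position"]),
        )
    except KeyError as exc:
        raise TableParseError(f"{path}: missing geometry key {exc}") from exc


def write_geometry(geometry: ReplicationGeometry, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "chromosome_id": geometry.chromosome_id,
                "length": geometry.length,
                "oric_position": geometry.oric_position,
                "ter_position": geometry.ter_position,
            },
            fh,
            sort_keys=False,
        )


def write_gene_table(records: Sequence[GeneRecord], path: str) -> None:
    """Write gene records as the canonical TSV dialect."""
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in records],
            "chromosome_id": [g.chromosome_id for g in records],
            "start": [g.start for g in records],
            "end": [g.end for g in records],
            "strand": ["+" if g.coding_strand == WATSON else "-" for g in records],
            "wraps": [int(g.wraps) for g in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_annotation_table(table: AnnotationTable, path: str) -> None:
    table.data.to_csv(path, sep="\t", float_format="%.6g")


RESULT_COLUMNS = [
    "genome",
    "n_binary", "binary_r", "binary_p",
    "n_fitness", "fitness_r", "fitness_p",
    "grouped_r", "grouped_p",
    "n_expression", "expression_r", "expression_p",
]


def write_results(rows: Iterable[dict], path: str) -> None:
    """Write per-genome correlation results as a round-trippable TSV.

    Each row is a mapping with a subset of the fixed result columns; absent
    entries are written as empty cells. Floats keep 6 significant digits.
    """
    df = pd.DataFrame(list(rows), columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
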