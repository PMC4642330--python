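"""Per-genome analysis orchestration and cross-genome paired comparisons.

One genome yields one result row: the correlation of each available
annotation column (binary essentiality, fitness, expression) with the 0/1
leading-strand vector, plus the decile-grouped fitness correlation. Genes
lacking a particular annotation are dropped for that column only (pairwise
deletion) — real coverage differs per source database. Across genomes,
fitness coefficients are sign-aligned (negated) and compared to the binary
or expression coefficients by a paired two-sided t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from strandbias.correlation_stats import (
    CorrelationResult,
    PairedComparison,
    align_sign,
    paired_ttest,
    pearson_with_p,
)
from strandbias.grouping_analysis import (
    GroupCorrelation,
    GroupSummary,
    group_correlation,
    group_equal_count,
    group_equal_interval,
    summarize_groups,
)
from strandbias.io_tables import (
    AnnotationTable,
    GeneRecord,
    ReplicationGeometry,
    StrandClassTable,
)
from strandbias.strand_assignment import classify_genome

logger = logging.getLogger(__name__)


@dataclass
class GenomeAnalysisRow:
    """Correlations of one genome's annotations with strand orientation.

    Each correlation is present only when its input column exists and the
    computation is defined; degenerate conditions (e.g. a constant strand
    vector) are recorded in ``notes`` instead of aborting the genome.
    """

    genome: str
    leading_fraction: float
    n_genes: int
    binary: CorrelationResult | None = None
    fitness: CorrelationResult | None = None
    expression: CorrelationResult | None = None
    grouped_equal_count: GroupCorrelation | None = None
    grouped_equal_interval: GroupCorrelation | None = None
    summaries_equal_count: list[GroupSummary] = field(default_factory=list)
    summaries_equal_interval: list[GroupSummary] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def as_result_dict(self) -> dict:
        """Flatten to the fixed result-TSV schema."""
        row: dict = {"genome": self.genome}
        for key, res in (("binary", self.binary), ("fitness", self.fitness),
                         ("expression", self.expression)):
            if res is not None:
                row[f"n_{key}"] = res.n
                row[f"{key}_r"] = res.r
                row[f"{key}_p"] = res.p_value
        if self.grouped_equal_count is not None:
            row["grouped_r"] = self.grouped_equal_count.r
            row["grouped_p"] = self.grouped_equal_count.p_value
        return row


def _column_correlation(values: pd.Series, strand_binary: pd.Series,
                        names: tuple[str, str]) -> CorrelationResult:
    aligned = strand_binary.reindex(values.index)
    if aligned.isna().any():
        missing = values.index[aligned.isna()][0]
        raise ValueError(f"gene {missing!r} annotated but not strand-classified")
    return pearson_with_p(values.to_numpy(), aligned.to_numpy(), names=names)


def analyze_genome(genes: list[GeneRecord], geometry: ReplicationGeometry,
                   annotations: AnnotationTable, genome: str = "",
                   k: int = 10, representative: str = "midpoint"
                   ) -> GenomeAnalysisRow:
    """Classify genes and correlate every available annotation column with
    leading-strand membership; run both grouping schemes when fitness is
    present."""
    usable = [c for c in ("fitness", "essential", "expression")
              if len(annotations.column(c))]
    if not usable:
        raise ValueError("no usable annotation columns (fitness/essential/expression)")
    strand, leading_fraction = classify_genome(
        genes, geometry, representative=representative
    )
    row = GenomeAnalysisRow(
        genome=genome or geometry.chromosome_id,
        leading_fraction=leading_fraction,
        n_genes=len(genes),
    )
    binary = strand.binary

    for attr, column, names in (
        ("binary", "essential", ("essential", "strand")),
        ("fitness", "fitness", ("fitness", "strand")),
        ("expression", "expression", ("expression", "strand")),
    ):
        values = annotations.column(column)
        if not len(values):
            continue
        try:
            setattr(row, attr, _column_correlation(values, binary, names))
        except ValueError as exc:
            row.notes.append(f"{column} vs strand: {exc}")
            logger.warning("%s: %s correlation skipped: %s", row.genome, column, exc)

    fitness = annotations.column("fitness")
    if len(fitness):
        for scheme, grouper, sum_attr, corr_attr in (
            ("equal_count", group_equal_count, "summaries_equal_count",
             "grouped_equal_count"),
            ("equal_interval", group_equal_interval, "summaries_equal_interval",
             "grouped_equal_interval"),
        ):
            try:
                assignment = grouper(fitness, k=k)
                summaries = summarize_groups(assignment, fitness, strand)
                setattr(row, sum_attr, summaries)
                setattr(row, corr_attr, group_correlation(summaries))
            except ValueError as exc:
                row.notes.append(f"{scheme} grouping: {exc}")
                logger.warning("%s: %s grouping skipped: %s",
                               row.genome, scheme, exc)
    for n_genes_col in usable:
        logger.info("%s: %d genes with %s", row.genome,
                    len(annotations.column(n_genes_col)), n_genes_col)
    return row


@dataclass(frozen=True)
class GenomeComparison:
    """Cross-genome paired t-test between sign-aligned fitness coefficients
    and a comparator column's coefficients."""

    comparison: str
    test: PairedComparison
    n_fitness_higher: int
    m: int

    @property
    def fraction_fitness_higher(self) -> float:
        return self.n_fitness_higher / self.m


def compare_genomes(rows: list[GenomeAnalysisRow], comparison: str,
                    sign_mode: str = "negate") -> GenomeComparison:
    """Paired comparison of fitness vs binary-essentiality (or expression)
    coefficients across genomes.

    ``sign_mode="negate"`` applies align_sign (the fitness coefficients'
    expected sign is negative); ``"abs"`` compares magnitudes instead.
    Also reports in how many genomes the aligned fitness coefficient
    exceeds the comparator's.
    """
    if comparison == "fitness_vs_binary":
        other = "binary"
    elif comparison == "fitness_vs_expression":
        other = "expression"
    else:
        raise ValueError(f"unknown comparison {comparison!r}")
    pairs = [
        (row.fitness.r, getattr(row, other).r)
        for row in rows
        if row.fitness is not None and getattr(row, other) is not None
    ]
    if len(pairs) < 2:
        raise ValueError(
            f"need at least 2 genomes with both coefficients, got {len(pairs)}"
        )
    fitness_r = np.array([p[0] for p in pairs])
    other_r = np.array([p[1] for p in pairs])
    if sign_mode == "negate":
        aligned = align_sign(fitness_r)
    elif sign_mode == "abs":
        aligned, other_r = np.abs(fitness_r), np.abs(other_r)
    else:
        raise ValueError(f"unknown sign_mode {sign_mode!r}")
    test = paired_ttest(aligned, other_r)
    return GenomeComparison(
        comparison=comparison,
        test=test,
        n_fitness_higher=int(np.sum(aligned > other_r)),
        m=len(pairs),
    )
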