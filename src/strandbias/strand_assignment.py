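"""Leading/lagging strand classification on a circular chromosome.

A circular bacterial chromosome is replicated bidirectionally from oriC:
the arc from oriC to ter in increasing-coordinate (Watson) direction is
copied by one fork, its complement by the other. A Watson-strand gene on
the ori->ter arc is co-oriented with its fork and sits on the leading
strand; a Crick-strand gene there is on the lagging strand; on the
complementary ter->ori arc the rule reverses.

Arc membership is half-open: the ori->ter arc contains oriC itself but not
ter, the ter->ori arc contains ter but not oriC, so the two arcs partition
every position. A gene's representative position defaults to its midpoint,
computed on the circle for genes wrapping the coordinate origin.
"""

from __future__ import annotations

import numpy as np

from strandbias.io_tables import (
    WATSON,
    GeneRecord,
    ReplicationGeometry,
    StrandClassTable,
)

import pandas as pd

LEADING = "leading"
LAGGING = "lagging"


def in_ori_to_ter_arc(positions, geometry: ReplicationGeometry):
    """Vectorized arc test; accepts scalars or arrays, no range validation."""
    pos = np.asarray(positions)
    ori, ter = geometry.oric_position, geometry.ter_position
    if ori < ter:
        return (pos >= ori) & (pos < ter)
    return (pos >= ori) | (pos < ter)


def position_in_ori_to_ter_arc(position: float, geometry: ReplicationGeometry) -> bool:
    """True iff ``position`` lies on the half-open arc [oriC, ter) traversed
    from oriC toward increasing coordinates, wrapping at length -> 1."""
    if not (1 <= position <= geometry.length):
        raise ValueError(
            f"position {position} outside chromosome [1, {geometry.length}]"
        )
    return bool(in_ori_to_ter_arc(position, geometry))


def gene_midpoint(gene: GeneRecord, length: int) -> float:
    """Midpoint of a gene on the circle, in [1, length].

    For a wrapped gene (start > end) the midpoint is taken along the arc
    start -> length -> 1 -> end.
    """
    if not gene.wraps:
        return (gene.start + gene.end) / 2.0
    span = gene.end + length - gene.start + 1
    return (gene.start - 1 + (span - 1) / 2.0) % length + 1


def _representative(gene: GeneRecord, geometry: ReplicationGeometry,
                    representative: str) -> float:
    if representative == "midpoint":
        return gene_midpoint(gene, geometry.length)
    if representative == "start":
        return float(gene.start)
    raise ValueError(f"unknown representative {representative!r}")


def classify_gene(gene: GeneRecord, geometry: ReplicationGeometry,
                  representative: str = "midpoint") -> str:
    """Classify one gene as ``"leading"`` or ``"lagging"``.

    Watson-strand genes on the ori->ter arc are leading; Crick-strand genes
    there are lagging; both flip on the complementary arc.
    """
    if gene.chromosome_id != geometry.chromosome_id:
        raise ValueError(
            f"gene {gene.gene_id!r} is on chromosome {gene.chromosome_id!r} "
            f"but geometry describes {geometry.chromosome_id!r}"
        )
    pos = _representative(gene, geometry, representative)
    if not (1 <= pos <= geometry.length):
        raise ValueError(
            f"gene {gene.gene_id!r}: representative position {pos} outside "
            f"chromosome [1, {geometry.length}]"
        )
    on_ori_ter = bool(in_ori_to_ter_arc(pos, geometry))
    if gene.coding_strand == WATSON:
        return LEADING if on_ori_ter else LAGGING
    return LAGGING if on_ori_ter else LEADING


def classify_genome(genes: list[GeneRecord], geometry: ReplicationGeometry,
                    representative: str = "midpoint"
                    ) -> tuple[StrandClassTable, float]:
    """Classify every gene; return the class table and the leading fraction."""
    if not genes:
        raise ValueError("cannot classify an empty gene list")
    for gene in genes:
        if gene.chromosome_id != geometry.chromosome_id:
            raise ValueError(
                f"gene {gene.gene_id!r} is on chromosome "
                f"{gene.chromosome_id!r} but geometry describes "
                f"{geometry.chromosome_id!r}"
            )
    pos = np.array([_representative(g, geometry, representative) for g in genes])
    if ((pos < 1) | (pos > geometry.length)).any():
        bad = np.argmax((pos < 1) | (pos > geometry.length))
        raise ValueError(
            f"gene {genes[bad].gene_id!r}: position {pos[bad]} outside "
            f"chromosome [1, {geometry.length}]"
        )
    on_arc = in_ori_to_ter_arc(pos, geometry)
    watson = np.array([g.coding_strand == WATSON for g in genes])
    leading = watson == on_arc
    classes = pd.Series(
        np.where(leading, LEADING, LAGGING),
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    table = StrandClassTable(classes)
    return table, float(leading.mean())


def replichore_arcs_bed(geometry: ReplicationGeometry) -> str:
    """The two replichore arcs as BED lines (0-based half-open)."""
    ori0 = geometry.oric_position - 1
    ter0 = geometry.ter_position - 1
    chrom, n = geometry.chromosome_id, geometry.length
    lines = []
    if ori0 < ter0:
        lines.append((chrom, ori0, ter0, "ori_to_ter"))
        lines.append((chrom, ter0, n, "ter_to_ori"))
        if ori0 > 0:
            lines.append((chrom, 0, ori0, "ter_to_ori"))
    else:
        lines.append((chrom, ori0, n, "ori_to_ter"))
        if ter0 > 0:
            lines.append((chrom, 0, ter0, "ori_to_ter"))
        lines.append((chrom, ter0, ori0, "ter_to_ori"))
    return "\n".join("\t".join(map(str, row)) for row in lines) + "\n"
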