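"""Geptop score -> fitness transform and DEG-style binary essentiality.

The Geptop essentiality score S of a gene is high when the gene looks
essential. Quantitative fitness is defined as f = 1 - S/Smax, where Smax is
the genome's maximum S excluding genes with S == 1; genes with S == 1 are
assigned fitness 0 directly. The quirk that both S = 1 and S = Smax map to
fitness 0 is part of the definition and is kept as-is.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Geptop exports finite-precision scores; S is compared to 1 after rounding
#: to this many decimal places rather than by strict float equality.
S_EQUALS_ONE_DECIMALS = 6


def geptop_to_fitness(scores: Mapping[str, float],
                      decimals: int = S_EQUALS_ONE_DECIMALS
                      ) -> dict[str, float]:
    """Map per-gene Geptop scores S to fitness in [0, 1].

    f = 0 where round(S, decimals) == 1, else f = 1 - S/Smax with Smax the
    maximum S over genes with S != 1. Raises on S < 0, S > 1, or when every
    gene has S == 1 (Smax undefined).
    """
    if not scores:
        raise ValueError("empty score set")
    for gene_id, s in scores.items():
        if s < 0:
            raise ValueError(f"gene {gene_id!r}: negative Geptop score {s}")
        if s > 1:
            raise ValueError(f"gene {gene_id!r}: Geptop score {s} > 1")
    is_one = {g: round(s, decimals) == 1.0 for g, s in scores.items()}
    rest = [s for g, s in scores.items() if not is_one[g]]
    if not rest:
        raise ValueError("all scores equal 1; Smax is undefined")
    smax = max(rest)
    if smax == 0:
        # every non-1 score is exactly 0: those genes get fitness 1
        return {g: 0.0 if is_one[g] else 1.0 for g in scores}
    return {
        g: 0.0 if is_one[g] else 1.0 - scores[g] / smax
        for g in scores
    }


def binary_essentiality(essential_ids: Iterable[str],
                        all_genes: Iterable[str]) -> dict[str, int]:
    """1 for genes recorded as essential, 0 for every other gene.

    Ids in ``essential_ids`` not present among ``all_genes`` are logged and
    ignored (database identifiers drift between releases).
    """
    genes = list(all_genes)
    if not genes:
        raise ValueError("empty gene list")
    gene_set = set(genes)
    essential = set(essential_ids)
    unknown = essential - gene_set
    if unknown:
        logger.warning(
            "%d essential ids not found in the gene list (e.g. %r); ignored",
            len(unknown), sorted(unknown)[0],
        )
    return {g: int(g in essential) for g in genes}
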