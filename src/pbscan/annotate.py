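"""Peak-SNP gene annotation: map retained windows to nearby genes.

Each retained window is represented by its peak SNP (the member with
the highest PBSn1); genes whose interval lies within a fixed radius
(default 5 kb) of that single position are collected, and the union
over a focal population's comparisons gives its final gene list.
Strand is ignored — this is proximity annotation, not regulatory
assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import GeneModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneHit:
    """A gene within ``radius`` of a peak SNP; distance 0 inside the gene."""

    gene_id: str
    chrom: str
    peak_pos: int
    distance: int


def genes_near(
    peak_position: int,
    chromosome: str,
    gene_models: Sequence[GeneModel],
    radius: int = 5000,
) -> list[GeneHit]:
    """Genes whose interval is within ``radius`` bp of a position (inclusive).

    Distance is 0 when the position falls inside the 1-based inclusive
    gene interval, otherwise the gap to the nearer end.  An unknown
    chromosome yields an empty list with a logged warning.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    on_chrom = [g for g in gene_models if g.chrom == chromosome]
    if not on_chrom:
        logger.warning("no gene models on chromosome %s", chromosome)
        return []
    hits = []
    for g in on_chrom:
        if g.start <= peak_position <= g.end:
            d = 0
        elif peak_position < g.start:
            d = g.start - peak_position
        else:
            d = peak_position - g.end
        if d <= radius:
            hits.append(GeneHit(g.gene_id, chromosome, peak_position, d))
    return hits


def build_gene_list(
    retained_by_comparison: Mapping[str, pd.DataFrame],
    gene_models: Sequence[GeneModel],
    radius: int = 5000,
) -> tuple[list[str], pd.DataFrame]:
    """Union of genes near peak SNPs over all comparisons of a focal population.

    ``retained_by_comparison`` maps comparison name -> retained-window
    table (with chrom, start_pos, peak_pos columns).  Returns the
    deduplicated, sorted gene list and a long-format provenance table
    (comparison, chrom, window start, peak position, gene, distance).
    """
    if not retained_by_comparison:
        raise ValueError("need at least one comparison")
    rows = []
    for comparison, windows in retained_by_comparison.items():
        for w in windows.itertuples():
            for hit in genes_near(int(w.peak_pos), w.chrom, gene_models, radius):
                rows.append({
                    "comparison": comparison,
                    "chrom": w.chrom,
                    "window_start": int(w.start_pos),
                    "peak_pos": hit.peak_pos,
                    "gene": hit.gene_id,
                    "distance": hit.distance,
                })
    provenance = pd.DataFrame(
        rows, columns=["comparison", "chrom", "window_start",
                       "peak_pos", "gene", "distance"]
    )
    gene_list = sorted(provenance["gene"].unique()) if len(provenance) else []
    if not gene_list:
        logger.warning("no gene within %d bp of any retained peak SNP", radius)
    return gene_list, provenance
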