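"""Classification of insertion sites against gene annotation.

Each site (the TTAA start position) is classified as exon or intron when
it falls inside a gene span, as 5' or 3' intergenic when it lies within
`window` bp (default 50 kb, inclusive) of the nearest gene edge, and
unassigned beyond that.  Upstream/downstream is resolved on the gene's
coding strand: a site before the TSS is 5' intergenic.

The window is measured from the nearest annotated gene-span edge (not
the TSS), the most common reading of "within 50 kb of known genes".
A site inside a gene is classified by the containing gene only, even if
another gene's window also covers it; among several nearby genes the
nearest edge wins, with exact ties broken by lexicographic gene id and
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from ._util import InputError, pct1
from .genome import GeneModel

logger = logging.getLogger(__name__)

CATEGORIES = ("exon", "intron", "intergenic_5p", "intergenic_3p", "unassigned")


@dataclass
class AnnotationIndex:
    """Interval lookups over gene spans and their +/- window neighbourhoods."""

    genes: list[GeneModel]
    window: int = 50_000

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}
        self._span_trees: dict[str, IntervalTree] = {}
        self._window_trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._span_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
            self._window_trees.setdefault(g.chrom, IntervalTree()).addi(
                max(0, g.start - self.window), g.end + self.window, g.gene_id
            )
        self.chroms = set(self._span_trees)

    def containing(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._span_trees.get(chrom)
        return sorted(
            (self._by_id[iv.data] for iv in (tree[pos] if tree else ())),
            key=lambda g: g.gene_id,
        )

    def nearby(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._window_trees.get(chrom)
        return sorted(
            (self._by_id[iv.data] for iv in (tree[pos] if tree else ())),
            key=lambda g: g.gene_id,
        )


@dataclass
class GeneAssignment:
    chrom: str
    ttaa_start: int
    pool: str
    support: int
    gene_id: str | None
    category: str
    distance: int  # 0 inside the gene; edge distance (1-based adjacency) otherwise


def _edge_distance(gene: GeneModel, pos: int) -> tuple[int, str]:
    """(distance, side) of an outside position; side is 'left' or 'right'."""
    if pos < gene.start:
        return gene.start - pos, "left"
    return pos - gene.end + 1, "right"


def classify_site(
    chrom: str,
    ttaa_start: int,
    annot: AnnotationIndex,
    pool: str = "",
    support: int = 0,
) -> GeneAssignment:
    """Classify one TTAA position; see module docstring for the rules."""
    if annot.chroms and chrom not in annot.chroms:
        raise InputError(f"unknown chromosome in site: {chrom}")
    inside = annot.containing(chrom, ttaa_start)
    if inside:
        if len(inside) > 1:
            logger.info("site %s:%d inside %d genes; keeping %s",
                        chrom, ttaa_start, len(inside), inside[0].gene_id)
        gene = inside[0]
        category = "exon" if gene.in_exon(ttaa_start) else "intron"
        return GeneAssignment(chrom, ttaa_start, pool, support, gene.gene_id, category, 0)

    nearby = [g for g in annot.nearby(chrom, ttaa_start)]
    scored = []
    for g in nearby:
        d, side = _edge_distance(g, ttaa_start)
        if d <= annot.window:
            scored.append((d, g.gene_id, g, side))
    if not scored:
        return GeneAssignment(chrom, ttaa_start, pool, support, None, "unassigned", 0)
    scored.sort()
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        logger.info("site %s:%d equidistant from %s and %s; keeping %s",
                    chrom, ttaa_start, scored[0][1], scored[1][1], scored[0][1])
    d, _, gene, side = scored[0]
    # 5' = upstream of the TSS on the coding strand
    if gene.strand == "+":
        category = "intergenic_5p" if side == "left" else "intergenic_3p"
    else:
        category = "intergenic_3p" if side == "left" else "intergenic_5p"
    return GeneAssignment(chrom, ttaa_start, pool, support, gene.gene_id, category, d)


def classify_sites(sites: pd.DataFrame, annot: AnnotationIndex) -> list[GeneAssignment]:
    """Classify every row of a site table (chrom, ttaa_start, pool, support)."""
    return [
        classify_site(row.chrom, int(row.ttaa_start), annot, row.pool, int(row.support))
        for row in sites.itertuples()
    ]


def breakdown_report(assignments: list[GeneAssignment], total_readable: int) -> dict:
    """Insertion-site accounting: near-gene yield and category percentages.

    Reports counts and one-decimal percentages (half-away-from-zero):
    near-gene sites over readable sequences, and — among near-gene
    sites — exon, intron and merged-intergenic fractions.  With 58
    near-gene of 504 readable the yield is 11.5%; 16 intergenic of 58
    is 27.6%.  Zero denominators report 0.0 and set `zero_denominator`.
    """
    counts = {c: 0 for c in CATEGORIES}
    for a in assignments:
        counts[a.category] += 1
    near_gene = sum(counts[c] for c in CATEGORIES if c != "unassigned")
    intergenic = counts["intergenic_5p"] + counts["intergenic_3p"]
    return {
        "counts": counts,
        "n_sites": len(assignments),
        "near_gene": near_gene,
        "total_readable": total_readable,
        "near_gene_pct": pct1(near_gene, total_readable),
        "exon_pct": pct1(counts["exon"], near_gene),
        "intron_pct": pct1(counts["intron"], near_gene),
        "intergenic_pct": pct1(intergenic, near_gene),
        "zero_denominator": total_readable == 0 or near_gene == 0,
    }


def assignments_frame(assignments: list[GeneAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [a.chrom for a in assignments],
            "ttaa_start": [a.ttaa_start for a in assignments],
            "pool": [a.pool for a in assignments],
            "support": [a.support for a in assignments],
            "gene_id": [a.gene_id for a in assignments],
            "category": [a.category for a in assignments],
            "distance": [a.distance for a in assignments],
        }
    )
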