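"""Differential candidate calling.

The screen contrasts two cell pools: ectopically arrested neurons (whose
insertions may have caused the arrest) and normally migrated cortical
neurons (whose insertions are tolerated passengers).  Genes hit in the
ectopic pool whose gene also appears in the cortical pool are excluded;
the remainder is the candidate list — e.g. 42 ectopic-pool genes with 9
overlapping the cortical pool yield 33 candidates.

Exclusion is at gene level by default (whole genes are excluded when
their insertions overlap between pools); a site-level variant that only
excludes genes sharing an identical TTAA is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import InputError
from .assign import GeneAssignment

_CATEGORY_PRIORITY = {"exon": 0, "intron": 1, "intergenic_5p": 2, "intergenic_3p": 2}


def _merged_category(categories: list[str]) -> str:
    """Representative insertion-position class for a gene (exon > intron > intergenic)."""
    best = min(categories, key=lambda c: _CATEGORY_PRIORITY[c])
    return "intergenic" if best.startswith("intergenic") else best


def pool_gene_sets(assignments: list[GeneAssignment], pool: str) -> pd.DataFrame:
    """Aggregate one pool's assignments into a per-gene table.

    Unassigned sites must be excluded upstream; intergenic assignments
    count toward the gene they were assigned to.  Columns: gene_id,
    sites (list of (chrom, ttaa_start)), n_distinct_sites, max_support,
    category, recurrent (>= 2 distinct sites).
    """
    if any(a.gene_id is None or a.category == "unassigned" for a in assignments):
        raise InputError("pool_gene_sets: unassigned sites must be filtered out first")
    by_gene: dict[str, list[GeneAssignment]] = {}
    for a in assignments:
        by_gene.setdefault(a.gene_id, []).append(a)
    rows = []
    for gene_id in sorted(by_gene):
        hits = by_gene[gene_id]
        sites = sorted({(a.chrom, a.ttaa_start) for a in hits})
        rows.append(
            {
                "gene_id": gene_id,
                "pool": pool,
                "sites": sites,
                "n_distinct_sites": len(sites),
                "max_support": max(a.support for a in hits),
                "category": _merged_category([a.category for a in hits]),
                "recurrent": len(sites) >= 2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "pool", "sites", "n_distinct_sites", "max_support",
                 "category", "recurrent"],
    )


@dataclass
class CandidateTable:
    table: pd.DataFrame
    provenance: dict  # n_ectopic_genes, n_overlap_genes, n_candidates


def differential_exclude(
    ectopic: pd.DataFrame, cortical: pd.DataFrame, site_level: bool = False
) -> CandidateTable:
    """Candidates = ectopic-pool genes absent from the cortical pool.

    With `site_level=True` a gene is only excluded when one of its
    ectopic TTAA sites is identical to a cortical site of the same gene.
    Provenance counts always satisfy
    n_candidates + n_overlap_genes = n_ectopic_genes.
    """
    ect_genes = list(ectopic["gene_id"]) if len(ectopic) else []
    if site_level:
        cort_sites = {
            (row.gene_id, site)
            for row in cortical.itertuples()
            for site in row.sites
        } if len(cortical) else set()
        overlap = {
            row.gene_id
            for row in ectopic.itertuples()
            if any((row.gene_id, site) in cort_sites for site in row.sites)
        }
    else:
        cort_genes = set(cortical["gene_id"]) if len(cortical) else set()
        overlap = {g for g in ect_genes if g in cort_genes}
    keep = ectopic[~ectopic["gene_id"].isin(overlap)].copy() if len(ectopic) else ectopic.copy()
    if len(keep):
        keep["evidence"] = ""  # free-text expression-evidence column for the user
    provenance = {
        "n_ectopic_genes": len(ect_genes),
        "n_overlap_genes": len(overlap),
        "n_candidates": len(keep),
    }
    return CandidateTable(table=keep.reset_index(drop=True), provenance=provenance)
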