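"""Flank mapping and insertion-site calling.

A self-contained seed-and-extend ungapped mapper places each genomic
flank on the toy reference; hit boundaries are then snapped to the TTAA
tetranucleotide the transposon occupied, and reads sharing a TTAA and
pool are collapsed into supported insertion sites ("major bands" when
support reaches `min_support`).

piggyBac integrates at TTAA with target-site duplication, so the TTAA
start is the canonical coordinate of a site.  Because the flank is
always reported reading adaptor -> transposon tag, the transposon lies
immediately beyond the mapped end of the flank:

  hit on '+' strand -> TTAA starts at the hit end,
  hit on '-' strand -> TTAA ends at the hit start.

Reads with two or more co-optimal placements are flagged non-unique and
excluded from site calling: for a screen, a false site is worse than a
lost read.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from ._util import revcomp
from .genome import ToyGenome


@dataclass
class ReferenceIndex:
    """Exact k-mer index over the forward strand of every chromosome."""

    k: int
    sequences: dict[str, str]
    seed_table: dict[str, list[tuple[str, int]]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("k must be >= 8")
        table: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in self.sequences.items():
            if len(seq) < self.k:
                warnings.warn(f"chromosome {chrom} shorter than k={self.k}; skipped")
                continue
            for i in range(len(seq) - self.k + 1):
                table[seq[i : i + self.k]].append((chrom, i))
        self.seed_table = dict(table)


def build_index(sequences: dict[str, str], k: int = 12) -> ReferenceIndex:
    if not sequences:
        raise ValueError("empty genome")
    return ReferenceIndex(k=k, sequences=sequences)


@dataclass
class MappedHit:
    read_id: str
    chrom: str
    strand: str  # '+' or '-'
    match_start: int  # 0-based
    match_length: int
    mismatches: int
    unique: bool


def map_flank(
    read_id: str,
    flank: str,
    index: ReferenceIndex,
    max_mismatches: int = 4,
) -> MappedHit | None:
    """Seed-and-extend ungapped alignment of one flank.

    Non-overlapping k-mer seeds are drawn from the query on both strands
    (pigeonhole: a query of length >= (b+1)*k with <= b mismatches always
    retains one exact seed).  Returns the best hit, flagged non-unique
    when two or more locations tie at the best score, or None when no
    location is within the mismatch budget.
    """
    flank = flank.upper()
    k = index.k
    if len(flank) < k:
        return None
    best_mm: int | None = None
    best_locs: set[tuple[str, int, str]] = set()
    for strand, query in (("+", flank), ("-", revcomp(flank))):
        m = len(query)
        offsets = list(range(0, m - k + 1, k))
        candidates = set()
        for off in offsets:
            for chrom, pos in index.seed_table.get(query[off : off + k], ()):
                start = pos - off
                if 0 <= start and start + m <= len(index.sequences[chrom]):
                    candidates.add((chrom, start))
        for chrom, start in candidates:
            ref = index.sequences[chrom][start : start + m]
            mm = sum(a != b for a, b in zip(query, ref))
            if mm > max_mismatches:
                continue
            if best_mm is None or mm < best_mm:
                best_mm = mm
                best_locs = {(chrom, start, strand)}
            elif mm == best_mm:
                best_locs.add((chrom, start, strand))
    if best_mm is None:
        return None
    chrom, start, strand = min(best_locs)
    return MappedHit(
        read_id=read_id,
        chrom=chrom,
        strand=strand,
        match_start=start,
        match_length=len(flank),
        mismatches=best_mm,
        unique=len(best_locs) == 1,
    )


def predicted_ttaa(hit: MappedHit) -> int:
    """Predicted TTAA start implied by a hit (transposon beyond the flank end)."""
    if hit.strand == "+":
        return hit.match_start + hit.match_length
    return hit.match_start - 4


def call_sites(
    hits: list[tuple[MappedHit, str]],
    genome: ToyGenome,
    min_support: int = 5,
    snap_window: int = 4,
) -> tuple[pd.DataFrame, dict]:
    """Collapse mapped reads into TTAA insertion sites per pool.

    Each unique hit's implied TTAA coordinate is snapped to the nearest
    indexed TTAA within `snap_window` bp (nearest wins; exact tie -> the
    leftmost, deterministically).  Reads sharing (chrom, TTAA, pool) are
    collapsed with summed support; `major` marks support >= min_support.
    Hits that are non-unique or have no TTAA nearby are dropped and
    counted in the drop report.  Output ordering is canonical, so the
    call is invariant to read order and idempotent.
    """
    drops = Counter()
    support: Counter = Counter()
    for hit, pool in hits:
        if not hit.unique:
            drops["non_unique"] += 1
            continue
        pred = predicted_ttaa(hit)
        ttaa_positions = genome.ttaa_index.get(hit.chrom, [])
        near = [p for p in ttaa_positions if abs(p - pred) <= snap_window]
        if not near:
            drops["no_ttaa_in_window"] += 1
            continue
        pos = min(near, key=lambda p: (abs(p - pred), p))
        assert genome.is_ttaa(hit.chrom, pos)
        support[(hit.chrom, pos, pool)] += 1
    rows = [
        {
            "chrom": chrom,
            "ttaa_start": pos,
            "pool": pool,
            "support": n,
            "major": n >= min_support,
        }
        for (chrom, pos, pool), n in sorted(support.items())
    ]
    sites = pd.DataFrame(rows, columns=["chrom", "ttaa_start", "pool", "support", "major"])
    return sites, dict(drops)


def write_sites_bed(sites: pd.DataFrame, path) -> None:
    """BED of TTAA intervals (0-based half-open); score = support, name = pool."""
    with open(path, "w") as fh:
        for row in sites.itertuples():
            fh.write(
                f"{row.chrom}\t{row.ttaa_start}\t{row.ttaa_start + 4}\t{row.pool}\t{row.support}\t.\n"
            )
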