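"""Splinkerette-PCR read processing.

A splinkerette product is sequenced from the ligated adaptor through the
genomic flank into the transposon terminal repeat.  This module detects
the adaptor at one end and a transposon terminal tag at the other,
trims both, and reports the intervening genomic flank in a canonical
orientation (reading adaptor -> tag), so a read and its reverse
complement parse to the identical fragment.

Matching is Hamming-distance over a sliding window (no indels), which is
adequate for Sanger-grade reads and keeps the matcher exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from ._util import InputError, pct1, revcomp

# Double-stranded splinkerette adaptor, as annealed before ligation onto
# Sau3AI (GATC) fragment ends.  A sequenced product begins with one of
# the two strands.
LONG_STRAND_ADAPTOR = "CGAAGAGTAACCGTTGCTAGGAGAGACCGTGGCTGAATGAGACTGGTGTCGACACTAGTGG"
SHORT_STRAND_ADAPTOR = "GATCCCACTAGTGTCGACACCAGTCTCTAATTTTTTTTTTCAAAAAAA"

# piggyBac terminal-repeat tags flanking the genomic sequence on the
# transposon side.  The screen's own primer sequences are configuration;
# these defaults are the ones the simulator embeds (both start with the
# canonical PB repeat CCCTAGAAAGATA).
PB_TAG_5P = "CCCTAGAAAGATAGTCTGCG"
PB_TAG_3P = "CCCTAGAAAGATAATCATAT"

REJECT_REASONS = ("none", "no_adaptor", "no_tag", "short_flank", "ambiguous_bases")


@dataclass
class AdaptorSet:
    """Adaptor and transposon-tag sequences plus matching tolerances."""

    long_strand: str = LONG_STRAND_ADAPTOR
    short_strand: str = SHORT_STRAND_ADAPTOR
    transposon_tag_5p: str = PB_TAG_5P
    transposon_tag_3p: str = PB_TAG_3P
    max_mismatches: int = 2
    min_flank: int = 20
    max_ambiguous_frac: float = 0.10

    def __post_init__(self) -> None:
        for name in ("long_strand", "short_strand", "transposon_tag_5p", "transposon_tag_3p"):
            seq = getattr(self, name).upper()
            if not seq or set(seq) - set("ACGTN"):
                raise InputError(f"{name}: must be a non-empty A/C/G/T/N string")
            setattr(self, name, seq)
        shortest = min(len(self.transposon_tag_5p), len(self.transposon_tag_3p))
        if not self.max_mismatches < shortest / 4:
            raise InputError("max_mismatches: must be < shortest tag length / 4")


@dataclass
class FlankFragment:
    """Outcome of parsing one read; failures carry a reject_reason."""

    read_id: str
    flank_seq: str
    transposon_side: str  # '5p' or '3p' ('' when unreadable before tag call)
    readable: bool
    reject_reason: str = "none"


def _mismatches_at(seq: str, pattern: str, start: int) -> int:
    return sum(a != b for a, b in zip(seq[start : start + len(pattern)], pattern))


def _prefix_match(seq: str, pattern: str, budget: int) -> int | None:
    """Mismatch count of `pattern` against the start of `seq`, or None."""
    if len(seq) < len(pattern):
        return None
    mm = _mismatches_at(seq, pattern, 0)
    return mm if mm <= budget else None


def _best_tag(seq: str, pattern: str, from_pos: int, budget: int) -> tuple[int, int] | None:
    """Best (mismatches, start) for `pattern` in seq[from_pos:]; ties -> rightmost.

    The tag terminates the product, so when a tag-like word also occurs
    inside the flank the rightmost equally good match is the structural one.
    """
    best: tuple[int, int] | None = None
    for start in range(from_pos, len(seq) - len(pattern) + 1):
        mm = _mismatches_at(seq, pattern, start)
        if mm <= budget and (best is None or mm < best[0] or (mm == best[0] and start > best[1])):
            best = (mm, start)
    return best


def detect_and_trim(read_id: str, read_seq: str, adaptors: AdaptorSet | None = None) -> FlankFragment:
    """Locate adaptor and transposon tag, trim, and orient the flank.

    The adaptor is sought at the very start of the read in both the given
    orientation and its reverse complement; the winning orientation is the
    one with the fewer adaptor mismatches (an exact tie is rejected as
    no_adaptor rather than risking a flank of uncertain orientation).
    Failures are encoded in reject_reason, never raised.
    """
    adaptors = adaptors or AdaptorSet()
    seq = read_seq.upper()
    if not seq:
        return FlankFragment(read_id, "", "", False, "no_adaptor")

    budget = adaptors.max_mismatches
    candidates = []  # (adaptor_mm, adaptor_len, oriented_seq)
    for oriented in (seq, revcomp(seq)):
        for adaptor in (adaptors.long_strand, adaptors.short_strand):
            mm = _prefix_match(oriented, adaptor, budget)
            if mm is not None:
                candidates.append((mm, len(adaptor), oriented))
    if not candidates:
        return FlankFragment(read_id, "", "", False, "no_adaptor")
    candidates.sort(key=lambda c: (c[0], -c[1]))
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0] \
            and candidates[0][2] != candidates[1][2]:
        # equally good adaptor match in both orientations: ambiguous product
        return FlankFragment(read_id, "", "", False, "no_adaptor")
    _, adaptor_len, oriented = candidates[0]

    tags = []  # (mm, start, side, tag_len)
    for side, tag in (("5p", adaptors.transposon_tag_5p), ("3p", adaptors.transposon_tag_3p)):
        hit = _best_tag(oriented, tag, adaptor_len, budget)
        if hit is not None:
            tags.append((hit[0], hit[1], side, len(tag)))
    if not tags:
        return FlankFragment(read_id, "", "", False, "no_tag")
    tags.sort(key=lambda t: (t[0], -t[1]))
    _, tag_start, side, _ = tags[0]

    flank = oriented[adaptor_len:tag_start]
    if len(flank) < adaptors.min_flank:
        return FlankFragment(read_id, flank, side, False, "short_flank")
    ambiguous = sum(1 for b in flank if b not in "ACGT")
    if ambiguous > adaptors.max_ambiguous_frac * len(flank):
        return FlankFragment(read_id, flank, side, False, "ambiguous_bases")
    return FlankFragment(read_id, flank, side, True, "none")


def batch_classify(
    reads: Iterable[tuple[str, str]], adaptors: AdaptorSet | None = None
) -> tuple[pd.DataFrame, dict]:
    """Parse a batch of (read_id, sequence) pairs.

    Returns the per-read fragment table and a yield summary with counts
    {total, readable, by reject_reason} plus the readable percentage
    rounded to one decimal (504 readable of 754 products -> 66.8).
    """
    adaptors = adaptors or AdaptorSet()
    fragments = [detect_and_trim(rid, seq, adaptors) for rid, seq in reads]
    table = pd.DataFrame(
        {
            "read_id": [f.read_id for f in fragments],
            "side": [f.transposon_side for f in fragments],
            "readable": [f.readable for f in fragments],
            "reject_reason": [f.reject_reason for f in fragments],
            "flank": [f.flank_seq for f in fragments],
        }
    )
    total = len(fragments)
    readable = int(sum(f.readable for f in fragments))
    by_reason = {r: 0 for r in REJECT_REASONS if r != "none"}
    for f in fragments:
        if not f.readable:
            by_reason[f.reject_reason] += 1
    summary = {
        "total": total,
        "readable": readable,
        "by_reason": by_reason,
        "readable_pct": pct1(readable, total),
    }
    return table, summary


def readable_percentage(readable: int, total: int) -> float:
    """Yield accounting rule: readable/total as a one-decimal percentage."""
    return pct1(readable, total)
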