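"""Small shared helpers: sequence ops, rounding, error types."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def pct1(num: float, den: float) -> float:
    """Percentage rounded to one decimal, half away from zero.

    This is the accounting convention used for all reported yield and
    breakdown percentages (e.g. 58/504 -> 11.5, 16/58 -> 27.6).
    Returns 0.0 for a zero denominator; callers flag that case.
    """
    if den == 0:
        return 0.0
    q = Decimal(num) / Decimal(den) * 100
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def scan_motif(seq: str, motif: str = "TTAA") -> list[int]:
    """All 0-based start positions of `motif` in `seq` (overlaps allowed)."""
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


class PbscreenError(Exception):
    """Base class for package errors."""


class ConfigError(PbscreenError):
    """Invalid simulation or run configuration; message names the field."""


class GenerationError(PbscreenError):
    """Synthetic-data generation could not satisfy a constraint."""


class AnnotationError(PbscreenError):
    """Gene model inconsistent with coding annotation (e.g. frame)."""


class InputError(PbscreenError):
    """Malformed or inconsistent user input."""
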