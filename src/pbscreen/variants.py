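"""Tumor/normal somatic-variant filter cascade.

Two caller channels are merged (SNVs from channel A, indels from channel
B, mirroring a MuTect + Virmid setup), then filtered in a fixed order:

  read depth >= 20 in both normal and lesion samples
  -> alternative-read count >= 4 in the lesion
  -> exclusion of known SNPs (by identifier list)
  -> exonic variants only
  -> removal of synonymous variants (coding indels are retained).

Every stage count is recorded in a FilterTrace and every dropped record
is attributed to exactly one stage; nothing vanishes silently.  Coding
effect is decided by translating the affected codon of the toy
transcript before and after the change with the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pysam
from Bio.Seq import Seq

from ._util import AnnotationError, InputError, revcomp
from .genome import GeneModel, ToyGenome


@dataclass
class VariantRecord:
    """One paired normal/lesion variant call (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    dp_normal: int
    dp_lesion: int
    ac_lesion: int
    caller: str  # 'channelA' or 'channelB'
    id: str | None = None  # known-SNP identifier when reported

    def __post_init__(self) -> None:
        if min(self.dp_normal, self.dp_lesion) < 0:
            raise InputError(f"{self.key}: negative depth")
        if self.ac_lesion > self.dp_lesion:
            raise InputError(f"{self.key}: AC_lesion exceeds DP_lesion")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def var_type(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"


@dataclass
class CodingAnnotation:
    gene_id: str | None
    region: str  # 'exonic' | 'non_exonic'
    effect: str  # 'synonymous' | 'nonsynonymous' | 'non_coding' | 'indel_coding'


@dataclass
class FilterTrace:
    """Record counts after each cascade stage (non-increasing past the merge)."""

    input: int
    caller_merge: int
    depth_pass: int = 0
    alt_count_pass: int = 0
    snp_pass: int = 0
    exonic_pass: int = 0
    nonsynonymous_pass: int = 0

    def as_tuple(self) -> tuple[int, ...]:
        return (self.input, self.caller_merge, self.depth_pass, self.alt_count_pass,
                self.snp_pass, self.exonic_pass, self.nonsynonymous_pass)


# ---------------------------------------------------------------------------
# VCF I/O (minimal VCFv4.2 with NORMAL/LESION samples, FORMAT DP:AD)

_VCF_HEADER = """##fileformat=VCFv4.2
##source=pbscreen
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tLESION
"""


def write_vcf(records: list[VariantRecord], path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    contigs = "".join(
        f"##contig=<ID={c},length={n}>\n" for c, n in (contig_lengths or {}).items()
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs))
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            ref_n = r.dp_lesion - r.ac_lesion
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.id or '.'}\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"DP:AD\t{r.dp_normal}:{r.dp_normal},0\t{r.dp_lesion}:{ref_n},{r.ac_lesion}\n"
            )


def read_vcf(path: str | Path, caller: str) -> list[VariantRecord]:
    records = []
    with pysam.VariantFile(str(path)) as vf:
        for lineno, rec in enumerate(vf, 1):
            try:
                normal = rec.samples["NORMAL"]
                lesion = rec.samples["LESION"]
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=rec.alts[0],
                        dp_normal=int(normal["DP"]),
                        dp_lesion=int(lesion["DP"]),
                        ac_lesion=int(lesion["AD"][1]),
                        caller=caller,
                        id=rec.id,
                    )
                )
            except (KeyError, TypeError, IndexError) as exc:
                raise InputError(f"{path}: malformed record {lineno}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Cascade


def merge_callers(
    channel_a: list[VariantRecord], channel_b: list[VariantRecord]
) -> tuple[list[VariantRecord], dict]:
    """SNVs from channel A, indels from channel B; misrouted records dropped.

    Duplicate (chrom, pos, ref, alt) keys are deduplicated, channel A
    taking precedence.  Returns (merged records, drop/dedup counts).
    """
    dropped_misrouted = 0
    merged: dict[tuple, VariantRecord] = {}
    duplicates = 0
    for rec in channel_a:
        if rec.var_type != "SNV":
            dropped_misrouted += 1
            continue
        if rec.key in merged:
            duplicates += 1
            continue
        merged[rec.key] = rec
    for rec in channel_b:
        if rec.var_type != "indel":
            dropped_misrouted += 1
            continue
        if rec.key in merged:
            duplicates += 1
            continue
        merged[rec.key] = rec
    info = {"n_input": len(channel_a) + len(channel_b),
            "dropped_misrouted": dropped_misrouted,
            "deduplicated": duplicates}
    return list(merged.values()), info


def _cds_sequence(gene: GeneModel, genome: ToyGenome) -> str:
    spliced = "".join(genome.slice(gene.chrom, s, e) for s, e in gene.exons)
    return revcomp(spliced) if gene.strand == "-" else spliced


def _cds_position(gene: GeneModel, pos0: int) -> int | None:
    """Map a genomic 0-based position into spliced CDS coordinates, or None."""
    offset = 0
    fwd = None
    for s, e in gene.exons:
        if s <= pos0 < e:
            fwd = offset + (pos0 - s)
            break
        offset += e - s
    if fwd is None:
        return None
    return fwd if gene.strand == "+" else gene.cds_length - 1 - fwd


def annotate_coding(
    record: VariantRecord, genes: list[GeneModel], genome: ToyGenome
) -> CodingAnnotation:
    """Classify a variant against the toy transcripts.

    An exonic SNV is translated at its codon before and after the
    substitution; an unchanged amino acid is synonymous.  Coding indels
    are reported as indel_coding (functionally retained downstream).
    Positions outside every exon are non_exonic, with the gene id kept
    when the variant is intronic.
    """
    pos0 = record.pos - 1
    container = None
    for gene in genes:
        if gene.chrom == record.chrom and gene.contains(pos0):
            container = gene
            if gene.in_exon(pos0):
                break
    if container is None or not container.in_exon(pos0):
        return CodingAnnotation(
            gene_id=container.gene_id if container else None,
            region="non_exonic",
            effect="non_coding",
        )
    gene = container
    if gene.cds_length % 3 != 0:
        raise AnnotationError(f"gene {gene.gene_id}: CDS length not a multiple of 3")
    if record.var_type == "indel":
        return CodingAnnotation(gene.gene_id, "exonic", "indel_coding")
    cds = _cds_sequence(gene, genome)
    cpos = _cds_position(gene, pos0)
    base = record.alt if gene.strand == "+" else revcomp(record.alt)
    ref_base = record.ref if gene.strand == "+" else revcomp(record.ref)
    if cds[cpos] != ref_base:
        raise AnnotationError(
            f"gene {gene.gene_id}: reference allele mismatch at {record.chrom}:{record.pos}"
        )
    ci = cpos // 3
    codon_before = cds[3 * ci : 3 * ci + 3]
    codon_after = codon_before[: cpos % 3] + base + codon_before[cpos % 3 + 1 :]
    aa_before = str(Seq(codon_before).translate())
    aa_after = str(Seq(codon_after).translate())
    effect = "synonymous" if aa_before == aa_after else "nonsynonymous"
    return CodingAnnotation(gene.gene_id, "exonic", effect)


@dataclass
class FilterResult:
    survivors: list[VariantRecord]
    trace: FilterTrace
    annotations: dict[tuple, CodingAnnotation]
    dropped: dict[str, list[tuple]] = field(default_factory=dict)


def apply_filters(
    records: list[VariantRecord],
    known_snps: set[str],
    genes: list[GeneModel],
    genome: ToyGenome,
    min_depth: int = 20,
    min_alt: int = 4,
    n_input: int | None = None,
) -> FilterResult:
    """Run the fixed-order cascade on merged records; see module docstring."""
    trace = FilterTrace(
        input=n_input if n_input is not None else len(records),
        caller_merge=len(records),
    )
    dropped: dict[str, list[tuple]] = {
        s: [] for s in ("depth", "alt_count", "known_snp", "non_exonic", "synonymous")
    }
    annotations: dict[tuple, CodingAnnotation] = {}

    deep = lambda r: r.dp_normal >= min_depth and r.dp_lesion >= min_depth
    stage = [r for r in records if deep(r)]
    dropped["depth"] = [r.key for r in records if not deep(r)]
    trace.depth_pass = len(stage)

    nxt = [r for r in stage if r.ac_lesion >= min_alt]
    dropped["alt_count"] = [r.key for r in stage if r.ac_lesion < min_alt]
    stage = nxt
    trace.alt_count_pass = len(stage)

    nxt = [r for r in stage if not (r.id and r.id in known_snps)]
    dropped["known_snp"] = [r.key for r in stage if r.id and r.id in known_snps]
    stage = nxt
    trace.snp_pass = len(stage)

    exonic = []
    for r in stage:
        ann = annotate_coding(r, genes, genome)
        annotations[r.key] = ann
        if ann.region == "exonic":
            exonic.append(r)
        else:
            dropped["non_exonic"].append(r.key)
    stage = exonic
    trace.exonic_pass = len(stage)

    survivors = []
    for r in stage:
        if annotations[r.key].effect == "synonymous":
            dropped["synonymous"].append(r.key)
        else:
            survivors.append(r)
    trace.nonsynonymous_pass = len(survivors)

    return FilterResult(survivors=survivors, trace=trace, annotations=annotations,
                        dropped=dropped)


def candidate_intersection(
    survivors: list[VariantRecord],
    annotations: dict[tuple, CodingAnnotation],
    panel: set[str],
    count_mutations: bool = False,
) -> tuple[set[str], int]:
    """Distinct mutated genes among survivors intersected with a candidate panel.

    By default k counts distinct overlapping genes; with
    `count_mutations=True` it counts the surviving variant records that
    fall in panel genes instead (a gene hit twice contributes 2).
    """
    if not panel:
        raise InputError("candidate panel is empty")
    genes = {annotations[r.key].gene_id for r in survivors if annotations[r.key].gene_id}
    overlap = genes & panel
    if count_mutations:
        k = sum(1 for r in survivors if annotations[r.key].gene_id in overlap)
    else:
        k = len(overlap)
    return overlap, k
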