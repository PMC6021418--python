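"""Reference containers and annotation/file I/O shared across the pipeline.

Coordinates are 0-based half-open internally; GFF3 and VCF output are
1-based inclusive, BED output is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import InputError, scan_motif

TTAA = "TTAA"


@dataclass
class GeneModel:
    """A toy gene: a span on one strand with disjoint sorted exons.

    The coding sequence is the concatenation of the exons (spliced),
    read on the annotated strand, in frame 0; its length must be a
    multiple of three for coding annotation.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # 0-based
    end: int  # exclusive
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"gene {self.gene_id}: strand must be + or -")
        if self.end <= self.start:
            raise InputError(f"gene {self.gene_id}: end must exceed start")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e <= s or e > self.end:
                raise InputError(
                    f"gene {self.gene_id}: exons must be sorted, disjoint and within the span"
                )
            prev = e

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class ToyGenome:
    """In-memory reference: uppercase A/C/G/T sequences plus a TTAA index.

    `ttaa_index` holds, per chromosome, the sorted 0-based start
    positions of every TTAA motif, recomputed by scanning so it can
    never drift from the sequence.
    """

    chrom_names: list[str]
    sequences: dict[str, str]

    ttaa_index: dict[str, list[int]] = field(init=False)

    def __post_init__(self) -> None:
        self.ttaa_index = {c: scan_motif(self.sequences[c], TTAA) for c in self.chrom_names}

    def slice(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]

    def is_ttaa(self, chrom: str, pos: int) -> bool:
        return self.slice(chrom, pos, pos + 4) == TTAA


# ---------------------------------------------------------------------------
# File I/O


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise InputError(f"{path}: FASTA record without an identifier")
        out[rec.id] = str(rec.seq).upper()
    return out


def load_genome(path: str | Path) -> ToyGenome:
    seqs = read_fasta(path)
    return ToyGenome(chrom_names=list(seqs), sequences=seqs)


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpbscreen\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tpbscreen\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene/exon models from GFF3 (exons linked to genes by Parent)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                            merge_strategy="create_unique")
    spans: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for f in db.features_of_type("gene"):
        spans[f.id] = (f.seqid, f.strand, f.start - 1, f.end)
    for f in db.features_of_type("exon"):
        for parent in f.attributes.get("Parent", []):
            exons.setdefault(parent, []).append((f.start - 1, f.end))
    out = []
    for gid, (chrom, strand, start, end) in spans.items():
        out.append(GeneModel(gid, chrom, strand, start, end, sorted(exons.get(gid, []))))
    return out


def write_bed(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
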