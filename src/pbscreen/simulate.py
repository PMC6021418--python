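"""Synthetic screen data: every input the pipeline consumes, with ground truth.

The generator emulates the structure of a transposon somatic-mutagenesis
screen:

* a toy genome whose genes are spaced far enough apart (>= 2x the 50-kb
  assignment window) that nearest-gene assignment is unambiguous, with
  TTAA motifs planted in every exon, intron and 5'/3' flank;
* clonally expanded piggyBac insertions in two cell pools — driver genes
  hit only in the ectopic pool, shared passenger genes hit in both, the
  remaining genes hit only in the cortical pool — plus low-support
  background sites;
* splinkerette reads built as adaptor + genomic flank + transposon tag,
  the flank running from the insertion TTAA to the nearest GATC (Sau3AI
  site), with configurable substitution errors and a truncated
  "unreadable" fraction;
* paired normal/lesion variant tables with one record class per filter
  stage (pass, low depth, low alt count, known SNP, intronic,
  synonymous, plus coding indels routed to the second caller channel);
* a per-cell cortical-bin table for the distribution statistics.

All outputs are byte-identical under a fixed config (seed included).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ConfigError, GenerationError, revcomp
from .genome import (GeneModel, ToyGenome, write_bed, write_fasta, write_gff3)
from .splink import AdaptorSet
from .variants import VariantRecord, annotate_coding, write_vcf

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class VariantCounts:
    """How many variant records to emit per planted truth class."""

    n_pass: int = 6
    n_low_depth: int = 3
    n_low_alt: int = 3
    n_known_snp: int = 3
    n_non_exonic: int = 4
    n_synonymous: int = 3
    n_pass_indel: int = 1

    @property
    def total(self) -> int:
        return (self.n_pass + self.n_low_depth + self.n_low_alt + self.n_known_snp
                + self.n_non_exonic + self.n_synonymous + self.n_pass_indel)


@dataclass
class SimConfig:
    """Study conditions for the synthetic screen."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 400_000
    n_genes: int = 6
    exons_per_gene: int = 3
    exon_length: int = 300
    intron_length: int = 1_500
    intergenic_window: int = 50_000
    n_driver_genes: int = 3
    n_shared_genes: int = 1
    clonal_reads_per_site: int = 20
    minor_read_rate: float = 0.1
    unreadable_fraction: float = 0.33
    base_error_rate: float = 0.0
    variant_counts: VariantCounts = field(default_factory=VariantCounts)

    def __post_init__(self) -> None:
        if self.n_driver_genes + self.n_shared_genes > self.n_genes:
            raise ConfigError("n_driver_genes: n_driver_genes + n_shared_genes must be <= n_genes")
        if self.chrom_length <= 2 * self.intergenic_window:
            raise ConfigError("chrom_length: must exceed 2 x intergenic_window")
        for name in ("minor_read_rate", "unreadable_fraction", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1]")
        if (self.exons_per_gene * self.exon_length) % 3 != 0:
            raise ConfigError("exon_length: total coding length must be a multiple of 3")
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise ConfigError("n_genes: need at least one chromosome and gene")
        if self.exons_per_gene < 2:
            raise ConfigError("exons_per_gene: need >= 2 exons so genes have introns")

    @property
    def gene_length(self) -> int:
        return (self.exons_per_gene * self.exon_length
                + (self.exons_per_gene - 1) * self.intron_length)


@dataclass
class Insertion:
    chrom: str
    ttaa_start: int
    pool: str  # 'ectopic' or 'cortical'
    gene_id: str | None
    intended_class: str  # 'exon' | 'intron' | 'background'
    n_reads: int


# ---------------------------------------------------------------------------
# Genome


def _prepared_positions(gene: GeneModel) -> list[tuple[int, str]]:
    """The deterministic (TTAA position, class) lattice planted inside a gene."""
    out = []
    for s, e in gene.exons:
        out.append((s + (e - s) // 2, "exon"))
    for (s1, e1), (s2, _e2) in zip(gene.exons, gene.exons[1:]):
        out.append((e1 + (s2 - e1) // 2, "intron"))
    return out


_FLANK_OFFSETS = (1_000, 10_000, 25_000, 49_000)


def generate_genome(config: SimConfig) -> tuple[ToyGenome, list[GeneModel]]:
    """Build the toy reference and annotation.

    Genes are placed 2x `intergenic_window` apart so the nearest-gene
    rule is never ambiguous; a TTAA is planted at the centre of every
    exon and intron and at fixed offsets into each 5'/3' flank.  Around
    every intragenic TTAA, GATC occurrences closer than 30 bp are
    scrubbed and one is guaranteed within 250 bp on each side, so every
    potential insertion yields a readable restriction flank.
    """
    rng = np.random.default_rng([config.seed, 0])
    gl = config.gene_length
    w = config.intergenic_window
    per_chrom: list[list[int]] = [[] for _ in range(config.n_chromosomes)]
    for g in range(config.n_genes):
        per_chrom[g % config.n_chromosomes].append(g)
    max_per = max(len(c) for c in per_chrom)
    needed = w + max_per * gl + (max_per - 1) * 2 * w + w
    if needed > config.chrom_length:
        raise ConfigError(
            f"n_genes: {max_per} genes of {gl} bp need {needed} bp per chromosome, "
            f"have {config.chrom_length}"
        )

    sequences: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = _BASES[rng.integers(0, 4, size=config.chrom_length)].copy()
        for slot, gi in enumerate(per_chrom[ci]):
            start = w + slot * (gl + 2 * w)
            exons = [
                (start + j * (config.exon_length + config.intron_length),
                 start + j * (config.exon_length + config.intron_length) + config.exon_length)
                for j in range(config.exons_per_gene)
            ]
            gene = GeneModel(
                gene_id=f"gene{gi + 1:02d}",
                chrom=chrom,
                strand="+" if gi % 2 == 0 else "-",
                start=start,
                end=start + gl,
                exons=exons,
            )
            genes.append(gene)
            for pos, _cls in _prepared_positions(gene):
                _plant_ttaa(seq, pos, rng)
            for off in _FLANK_OFFSETS:
                if off <= w:
                    left = start - off
                    right = gene.end + off - 1
                    if left >= 0:
                        seq[left:left + 4] = np.frombuffer(b"TTAA", dtype="S1")
                    if right + 4 <= len(seq):
                        seq[right:right + 4] = np.frombuffer(b"TTAA", dtype="S1")
        sequences[chrom] = seq

    seq_strings = {c: s.tobytes().decode() for c, s in sequences.items()}
    genome = ToyGenome(chrom_names=list(seq_strings), sequences=seq_strings)
    for gene in genes:
        if not any(gene.start <= p < gene.end for p in genome.ttaa_index[gene.chrom]):
            raise GenerationError(f"gene {gene.gene_id} contains no TTAA")
    return genome, genes


def _plant_ttaa(seq: np.ndarray, pos: int, rng: np.random.Generator) -> None:
    """Write a TTAA at `pos` and normalise its GATC environment."""
    seq[pos:pos + 4] = np.frombuffer(b"TTAA", dtype="S1")
    text = seq[max(0, pos - 300):pos + 304].tobytes().decode()
    base = max(0, pos - 300)
    # scrub GATC within 30 bp of the motif (either side)
    i = text.find("GATC")
    while i != -1:
        g = base + i
        if (pos - 34 <= g <= pos - 1 or pos + 4 <= g <= pos + 33) and not pos <= g < pos + 4:
            seq[g] = b"C"
        i = text.find("GATC", i + 1)
    text = seq[max(0, pos - 300):pos + 304].tobytes().decode()
    # guarantee a cut site within [60, 250] bp on each side
    left = text[:pos - base]
    if "GATC" not in left[-250:-60]:
        d = int(rng.integers(60, 247))
        seq[pos - d - 4:pos - d] = np.frombuffer(b"GATC", dtype="S1")
    right = text[pos - base + 4:]
    if "GATC" not in right[60:250]:
        d = int(rng.integers(60, 247))
        seq[pos + 4 + d:pos + 8 + d] = np.frombuffer(b"GATC", dtype="S1")


# ---------------------------------------------------------------------------
# Insertions


def plant_insertions(
    genome: ToyGenome, genes: list[GeneModel], config: SimConfig
) -> tuple[list[Insertion], dict]:
    """Assign driver / shared / passenger roles and plant clonal insertions.

    Driver genes receive an ectopic-pool insertion at a TTAA inside the
    gene; shared genes receive insertions in both pools at the same
    TTAA; every remaining gene becomes a cortical-only passenger.  Each
    clonal site carries `clonal_reads_per_site` reads; background sites
    of support 1 are added so that minor reads are a `minor_read_rate`
    fraction of the clonal reads in each pool.
    """
    rng = np.random.default_rng([config.seed, 1])
    order = [genes[i] for i in rng.permutation(len(genes))]
    drivers = order[: config.n_driver_genes]
    shared = order[config.n_driver_genes: config.n_driver_genes + config.n_shared_genes]
    passengers = order[config.n_driver_genes + config.n_shared_genes:]

    def pick_site(gene: GeneModel) -> tuple[int, str]:
        lattice = _prepared_positions(gene)
        usable = [(p, c) for p, c in lattice if genome.is_ttaa(gene.chrom, p)]
        if not usable:
            raise GenerationError(f"gene {gene.gene_id}: no TTAA available in target region")
        return usable[int(rng.integers(0, len(usable)))]

    insertions: list[Insertion] = []
    for gene in drivers:
        pos, cls = pick_site(gene)
        insertions.append(Insertion(gene.chrom, pos, "ectopic", gene.gene_id, cls,
                                    config.clonal_reads_per_site))
    for gene in shared:
        pos, cls = pick_site(gene)
        for pool in ("ectopic", "cortical"):
            insertions.append(Insertion(gene.chrom, pos, pool, gene.gene_id, cls,
                                        config.clonal_reads_per_site))
    for gene in passengers:
        pos, cls = pick_site(gene)
        insertions.append(Insertion(gene.chrom, pos, "cortical", gene.gene_id, cls,
                                    config.clonal_reads_per_site))

    for pool in ("ectopic", "cortical"):
        n_major_reads = sum(i.n_reads for i in insertions if i.pool == pool)
        n_minor = int(rng.binomial(n_major_reads, config.minor_read_rate))
        for _ in range(n_minor):
            chrom = genome.chrom_names[int(rng.integers(0, len(genome.chrom_names)))]
            positions = genome.ttaa_index[chrom]
            pos = positions[int(rng.integers(0, len(positions)))]
            insertions.append(Insertion(chrom, pos, pool, None, "background", 1))

    truth = {
        "driver_genes": sorted(g.gene_id for g in drivers),
        "shared_genes": sorted(g.gene_id for g in shared),
        "passenger_genes": sorted(g.gene_id for g in passengers),
    }
    return insertions, truth


# ---------------------------------------------------------------------------
# Reads


def synthesize_splinkerette_reads(
    genome: ToyGenome,
    insertions: list[Insertion],
    config: SimConfig,
    adaptors: AdaptorSet | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], int]:
    """Build splinkerette products for every insertion.

    Reads alternate between the 5' and 3' side of the insertion.  A
    5'-side product is adaptor + genome[GATC..TTAA) + 5' tag; a 3'-side
    product carries the reverse complement of genome[TTAA..GATC) so the
    flank always reads away from the transposon.  A random half of the
    products is emitted reverse-complemented, substitution errors are
    applied at `base_error_rate`, and an `unreadable_fraction` of reads
    has its flank truncated below the readable minimum.  Reads whose
    flank would be empty (GATC adjacent to the TTAA) are skipped and
    counted.
    """
    adaptors = adaptors or AdaptorSet()
    rng = np.random.default_rng([config.seed, 2])
    reads: dict[str, list[tuple[str, str]]] = {"ectopic": [], "cortical": []}
    skipped = 0
    for ins in insertions:
        seq = genome.sequences[ins.chrom]
        for i in range(ins.n_reads):
            side = "5p" if i % 2 == 0 else "3p"
            if side == "5p":
                g = seq.rfind("GATC", 0, ins.ttaa_start)
                flank = seq[g + 4: ins.ttaa_start] if g != -1 else ""
                tag = adaptors.transposon_tag_5p
            else:
                g = seq.find("GATC", ins.ttaa_start + 4)
                flank = revcomp(seq[ins.ttaa_start + 4: g]) if g != -1 else ""
                tag = adaptors.transposon_tag_3p
            if not flank:
                skipped += 1
                continue
            if rng.random() < config.unreadable_fraction:
                flank = flank[: int(rng.integers(0, adaptors.min_flank))]
            adaptor = adaptors.long_strand if rng.random() < 0.5 else adaptors.short_strand
            read = adaptor + flank + tag
            if config.base_error_rate > 0:
                arr = np.frombuffer(read.encode(), dtype="S1").copy()
                hits = np.nonzero(rng.random(len(arr)) < config.base_error_rate)[0]
                for h in hits:
                    choices = [b for b in b"ACGT" if bytes([b]) != arr[h]]
                    arr[h] = bytes([choices[int(rng.integers(0, 3))]])
                read = arr.tobytes().decode()
            if rng.random() < 0.5:
                read = revcomp(read)
            rid = f"{ins.pool}:{ins.chrom}:{ins.ttaa_start}:{i}"
            reads[ins.pool].append((rid, read))
    return reads, skipped


# ---------------------------------------------------------------------------
# Somatic variants


def _random_depths(rng) -> tuple[int, int, int]:
    dp_n = int(rng.integers(30, 81))
    dp_l = int(rng.integers(40, 91))
    ac = int(rng.integers(6, 16))
    return dp_n, dp_l, ac


def simulate_somatic_variants(
    genome: ToyGenome,
    genes: list[GeneModel],
    config: SimConfig,
    prefer_genes: list[str] | None = None,
) -> tuple[list[VariantRecord], list[VariantRecord], list[str], list[dict]]:
    """Emit paired-sample variant records per planted truth class.

    Pass-class records are exonic nonsynonymous SNVs with DP >= 20 in
    both samples and AC >= 4, placed preferentially in `prefer_genes`
    (so panel-intersection truth is controlled); each failure class
    violates exactly one filter stage.  SNVs go to channel A, indels to
    channel B.  Returns (channel A, channel B, known-SNP ids, truth).
    """
    rng = np.random.default_rng([config.seed, 3])
    vc = config.variant_counts
    by_id = {g.gene_id: g for g in genes}
    prefer = [by_id[g] for g in prefer_genes] if prefer_genes else list(genes)
    used: set[tuple[str, int]] = set()

    def exonic_snv(gene_cycle: list[GeneModel], want_synonymous: bool) -> VariantRecord | None:
        for gene in gene_cycle:
            positions = [p for s, e in gene.exons for p in range(s, e)]
            rng.shuffle(positions)
            for pos0 in positions:
                if (gene.chrom, pos0) in used:
                    continue
                ref = genome.slice(gene.chrom, pos0, pos0 + 1)
                alts = [b for b in "ACGT" if b != ref]
                rng.shuffle(alts)
                for alt in alts:
                    rec = VariantRecord(gene.chrom, pos0 + 1, ref, alt, 50, 60, 10, "channelA")
                    ann = annotate_coding(rec, genes, genome)
                    if (ann.effect == "synonymous") == want_synonymous:
                        used.add((gene.chrom, pos0))
                        return rec
        return None

    def place(gene_cycle, want_synonymous=False) -> VariantRecord:
        rec = exonic_snv(gene_cycle, want_synonymous)
        if rec is None:
            kind = "synonymous" if want_synonymous else "nonsynonymous"
            raise GenerationError(f"no exonic position available for a {kind} variant")
        return rec

    channel_a: list[VariantRecord] = []
    channel_b: list[VariantRecord] = []
    known: list[str] = []
    truth: list[dict] = []

    def cyc(i: int, pool: list[GeneModel]) -> list[GeneModel]:
        return pool[i % len(pool):] + pool[: i % len(pool)]

    def emit(rec: VariantRecord, cls: str) -> None:
        (channel_b if rec.var_type == "indel" else channel_a).append(rec)
        truth.append({"key": list(rec.key), "class": cls})

    for i in range(vc.n_pass):
        rec = place(cyc(i, prefer))
        rec.dp_normal, rec.dp_lesion, rec.ac_lesion = _random_depths(rng)
        emit(rec, "pass")
    for i in range(vc.n_low_depth):
        rec = place(cyc(i, list(genes)))
        _, rec.dp_lesion, rec.ac_lesion = _random_depths(rng)
        rec.dp_normal = int(rng.integers(5, 20))
        emit(rec, "fail_depth")
    for i in range(vc.n_low_alt):
        rec = place(cyc(i + 1, list(genes)))
        rec.dp_normal, rec.dp_lesion, _ = _random_depths(rng)
        rec.ac_lesion = int(rng.integers(1, 4))
        emit(rec, "fail_alt_count")
    for i in range(vc.n_known_snp):
        rec = place(cyc(i + 2, list(genes)))
        rec.dp_normal, rec.dp_lesion, rec.ac_lesion = _random_depths(rng)
        rec.id = f"rs{900000 + i}"
        known.append(rec.id)
        emit(rec, "known_snp")
    for i in range(vc.n_non_exonic):
        gene = genes[i % len(genes)]
        s, e = gene.exons[0][1], gene.exons[1][0]  # first intron
        pos0 = next(p for p in range(s + 20 + i, e) if (gene.chrom, p) not in used)
        used.add((gene.chrom, pos0))
        ref = genome.slice(gene.chrom, pos0, pos0 + 1)
        alt = next(b for b in "ACGT" if b != ref)
        dp_n, dp_l, ac = _random_depths(rng)
        emit(VariantRecord(gene.chrom, pos0 + 1, ref, alt, dp_n, dp_l, ac, "channelA"),
             "non_exonic")
    for i in range(vc.n_synonymous):
        rec = place(cyc(i + 3, list(genes)), want_synonymous=True)
        rec.dp_normal, rec.dp_lesion, rec.ac_lesion = _random_depths(rng)
        emit(rec, "synonymous")
    for i in range(vc.n_pass_indel):
        gene = prefer[i % len(prefer)]
        s, e = gene.exons[-1]
        pos0 = next(p for p in range(s + 5 + i, e) if (gene.chrom, p) not in used)
        used.add((gene.chrom, pos0))
        ref = genome.slice(gene.chrom, pos0, pos0 + 1)
        dp_n, dp_l, ac = _random_depths(rng)
        emit(VariantRecord(gene.chrom, pos0 + 1, ref, ref + "ACT", dp_n, dp_l, ac,
                           "channelB"), "pass")

    known += [f"rs{800000 + j}" for j in range(5)]  # decoys never emitted
    return channel_a, channel_b, known, truth


# ---------------------------------------------------------------------------
# Cell-position tables


def simulate_cell_table(
    seed: int,
    n_animals: int = 3,
    cells_per_animal: int = 150,
    conditions: dict[str, tuple[float, float, float]] | None = None,
) -> pd.DataFrame:
    """Per-cell cortical-bin labels for >= 2 conditions.

    Defaults emulate a knockdown experiment: control cells mostly reach
    the cortical plate, knockdown cells accumulate in IZ and VZ/SVZ.
    Probabilities are per (CP, IZ, VZ/SVZ).
    """
    conditions = conditions or {
        "scramble": (0.60, 0.25, 0.15),
        "shRNA": (0.30, 0.30, 0.40),
    }
    rng = np.random.default_rng([seed, 4])
    bins = ("CP", "IZ", "VZ/SVZ")
    rows = []
    for cond, probs in conditions.items():
        for a in range(n_animals):
            labels = rng.choice(bins, size=cells_per_animal, p=probs)
            rows += [{"animal": f"{cond}_{a + 1}", "condition": cond, "bin": b}
                     for b in labels]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Top-level output writer


def simulate_all(config: SimConfig, outdir: str | Path) -> dict:
    """Generate and write every pipeline input plus truth.json.

    Files: genome.fasta, genes.gff3, genes.bed, reads_ectopic.fasta,
    reads_cortical.fasta, variants_channelA.vcf, variants_channelB.vcf,
    known_snps.txt, cells.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = generate_genome(config)
    insertions, roles = plant_insertions(genome, genes, config)
    reads, skipped = synthesize_splinkerette_reads(genome, insertions, config)
    channel_a, channel_b, known, var_truth = simulate_somatic_variants(
        genome, genes, config, prefer_genes=roles["driver_genes"]
    )
    cells = simulate_cell_table(config.seed)

    write_fasta(genome.sequences, outdir / "genome.fasta")
    write_gff3(genes, outdir / "genes.gff3")
    write_bed(genes, outdir / "genes.bed")
    for pool in ("ectopic", "cortical"):
        write_fasta(dict(reads[pool]), outdir / f"reads_{pool}.fasta")
    contigs = {c: len(s) for c, s in genome.sequences.items()}
    write_vcf(channel_a, outdir / "variants_channelA.vcf", contigs)
    write_vcf(channel_b, outdir / "variants_channelB.vcf", contigs)
    (outdir / "known_snps.txt").write_text("".join(f"{s}\n" for s in known))
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)

    truth = {
        "config": dataclasses.asdict(config),
        **roles,
        "insertions": [dataclasses.asdict(i) for i in insertions],
        "variants": var_truth,
        "skipped_reads": skipped,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {
        "genome": genome,
        "genes": genes,
        "insertions": insertions,
        "roles": roles,
        "reads": reads,
        "skipped_reads": skipped,
        "channel_a": channel_a,
        "channel_b": channel_b,
        "known_snps": known,
        "variant_truth": var_truth,
        "cells": cells,
    }
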