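"""Generator correctness: determinism, motif placement, planted truth."""

import hashlib
from pathlib import Path

import pytest
from Bio.Seq import Seq

from conftest import scan_ttaa_oracle
from pbscreen._util import ConfigError, revcomp
from pbscreen.simulate import (
    SimConfig,
    VariantCounts,
    generate_genome,
    plant_insertions,
    simulate_all,
    simulate_somatic_variants,
    synthesize_splinkerette_reads,
)
from pbscreen.splink import AdaptorSet


def _dir_hashes(d: Path) -> dict[str, str]:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(d.iterdir())}


def test_identical_config_gives_byte_identical_outputs(tmp_path):
    cfg = SimConfig(seed=1)
    simulate_all(cfg, tmp_path / "a")
    simulate_all(SimConfig(seed=1), tmp_path / "b")
    assert _dir_hashes(tmp_path / "a") == _dir_hashes(tmp_path / "b")


@pytest.mark.parametrize(
    "kwargs, field",
    [
        ({"chrom_length": 90_000, "intergenic_window": 50_000}, "chrom_length"),
        ({"n_driver_genes": 5, "n_shared_genes": 2, "n_genes": 6}, "n_driver_genes"),
        ({"minor_read_rate": 1.5}, "minor_read_rate"),
        ({"exon_length": 100, "exons_per_gene": 2}, "exon_length"),
    ],
)
def test_invalid_config_raises_naming_the_field(kwargs, field):
    with pytest.raises(ConfigError, match=field):
        SimConfig(**kwargs)


def test_ttaa_index_verified_by_full_scan(toy_genome):
    genome, _ = toy_genome
    for chrom in genome.chrom_names:
        seq = genome.sequences[chrom]
        for pos in genome.ttaa_index[chrom]:
            assert seq[pos : pos + 4] == "TTAA"
        assert genome.ttaa_index[chrom] == scan_ttaa_oracle(seq)


def test_every_gene_region_contains_ttaa(toy_genome):
    genome, genes = toy_genome
    for g in genes:
        assert any(g.start <= p < g.end for p in genome.ttaa_index[g.chrom])


def test_planted_roles_match_config(clean_config, clean_sim):
    roles = clean_sim["roles"]
    insertions = clean_sim["insertions"]
    assert len(roles["driver_genes"]) == clean_config.n_driver_genes
    assert len(roles["shared_genes"]) == clean_config.n_shared_genes
    pools_by_gene = {}
    for ins in insertions:
        if ins.gene_id:
            pools_by_gene.setdefault(ins.gene_id, set()).add(ins.pool)
    for g in roles["driver_genes"]:
        assert pools_by_gene[g] == {"ectopic"}
    for g in roles["shared_genes"]:
        assert pools_by_gene[g] == {"ectopic", "cortical"}
    for g in roles["passenger_genes"]:
        assert pools_by_gene[g] == {"cortical"}


def test_all_insertions_on_ttaa_and_clonal_support(toy_genome):
    genome, genes = toy_genome
    cfg = SimConfig(seed=5, n_chromosomes=1, chrom_length=350_000, n_genes=2,
                    n_driver_genes=1, n_shared_genes=1, minor_read_rate=0.0)
    insertions, _ = plant_insertions(genome, genes, cfg)
    for ins in insertions:
        assert ins.ttaa_start in genome.ttaa_index[ins.chrom]
        assert ins.n_reads == cfg.clonal_reads_per_site  # minor_read_rate=0


def test_error_free_read_carries_exact_restriction_flank(toy_genome):
    genome, genes = toy_genome
    cfg = SimConfig(seed=5, n_chromosomes=1, chrom_length=350_000, n_genes=2,
                    n_driver_genes=1, n_shared_genes=0, minor_read_rate=0.0,
                    unreadable_fraction=0.0, clonal_reads_per_site=2)
    insertions, _ = plant_insertions(genome, genes, cfg)
    ins = insertions[0]
    reads, skipped = synthesize_splinkerette_reads(genome, [ins], cfg)
    assert skipped == 0
    seq = genome.sequences[ins.chrom]
    g5 = seq.rfind("GATC", 0, ins.ttaa_start)
    flank5 = seq[g5 + 4 : ins.ttaa_start]
    g3 = seq.find("GATC", ins.ttaa_start + 4)
    flank3 = revcomp(seq[ins.ttaa_start + 4 : g3])
    expected = {flank5, flank3}
    for _rid, read in reads[ins.pool]:
        assert any(f in read or f in revcomp(read) for f in expected)


def test_reads_begin_with_a_printed_adaptor_strand(clean_sim):
    """As sequenced, every product starts with one of the two adaptor strands
    (records may be emitted on either strand of the product)."""
    ad = AdaptorSet()
    for pool in ("ectopic", "cortical"):
        for _rid, read in clean_sim["reads"][pool]:
            assert (
                read.startswith(ad.long_strand)
                or read.startswith(ad.short_strand)
                or revcomp(read).startswith(ad.long_strand)
                or revcomp(read).startswith(ad.short_strand)
            )


def test_unreadable_fraction_yield_within_binomial_interval(toy_genome):
    genome, genes = toy_genome
    cfg = SimConfig(seed=9, n_chromosomes=1, chrom_length=350_000, n_genes=2,
                    n_driver_genes=2, n_shared_genes=0, minor_read_rate=0.0,
                    unreadable_fraction=0.33, clonal_reads_per_site=150)
    insertions, _ = plant_insertions(genome, genes, cfg)
    reads, _ = synthesize_splinkerette_reads(genome, insertions, cfg)
    flat = reads["ectopic"] + reads["cortical"]
    assert len(flat) == 300
    from pbscreen.splink import batch_classify

    _table, summary = batch_classify(flat)
    # expect ~0.67 * 300 = 201 readable; 4 sigma of Binomial(300, 0.67) ~ 33
    assert abs(summary["readable"] - 201) < 35


def test_synonymous_class_preserves_amino_acid(toy_genome):
    """Codon-table oracle: translate the affected codon before/after."""
    genome, genes = toy_genome
    cfg = SimConfig(seed=5, n_chromosomes=1, chrom_length=350_000, n_genes=2,
                    n_driver_genes=1, n_shared_genes=1)
    a, b, _known, truth = simulate_somatic_variants(genome, genes, cfg)
    by_key = {tuple(t["key"]): t["class"] for t in truth}
    checked = 0
    for rec in a:
        if by_key[rec.key] != "synonymous":
            continue
        gene = next(g for g in genes if g.contains(rec.pos - 1) and g.in_exon(rec.pos - 1))
        spliced = "".join(genome.sequences[gene.chrom][s:e] for s, e in gene.exons)
        offset = 0
        for s, e in gene.exons:
            if s <= rec.pos - 1 < e:
                fwd = offset + (rec.pos - 1 - s)
                break
            offset += e - s
        mutated = spliced[:fwd] + rec.alt + spliced[fwd + 1 :]
        if gene.strand == "-":
            spliced, mutated = revcomp(spliced), revcomp(mutated)
        assert Seq(spliced).translate() == Seq(mutated).translate()
        checked += 1
    assert checked == cfg.variant_counts.n_synonymous


def test_gff3_round_trip_preserves_gene_models(clean_sim):
    from pbscreen.genome import read_gff3

    back = read_gff3(clean_sim["outdir"] / "genes.gff3")
    assert sorted(back, key=lambda g: g.gene_id) == sorted(
        clean_sim["genes"], key=lambda g: g.gene_id
    )


def test_variant_truth_classes_have_promised_properties(clean_sim):
    by_class: dict[str, list] = {}
    recs = {r.key: r for r in clean_sim["channel_a"] + clean_sim["channel_b"]}
    for t in clean_sim["variant_truth"]:
        by_class.setdefault(t["class"], []).append(recs[tuple(t["key"])])
    for rec in by_class["fail_depth"]:
        assert min(rec.dp_normal, rec.dp_lesion) < 20
    for rec in by_class["fail_alt_count"]:
        assert rec.ac_lesion < 4
    for rec in by_class["known_snp"]:
        assert rec.id in set(clean_sim["known_snps"])
    for rec in by_class["pass"]:
        assert rec.dp_normal >= 20 and rec.dp_lesion >= 20 and rec.ac_lesion >= 4
        assert rec.id is None
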