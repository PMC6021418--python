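"""Caller merging, the filter cascade, and coding annotation."""

import itertools

import pytest
from Bio.Seq import Seq

from pbscreen._util import AnnotationError, InputError, revcomp
from pbscreen.genome import GeneModel, ToyGenome
from pbscreen.simulate import SimConfig, VariantCounts, simulate_somatic_variants
from pbscreen.variants import (
    VariantRecord,
    annotate_coding,
    apply_filters,
    candidate_intersection,
    merge_callers,
    read_vcf,
    write_vcf,
)


def _rec(pos=100, ref="A", alt="C", dp_n=50, dp_l=60, ac=10, caller="channelA",
         chrom="c1", id=None):
    return VariantRecord(chrom, pos, ref, alt, dp_n, dp_l, ac, caller, id)


# ---------------------------------------------------------------------------
# merge_callers


def test_routing_keeps_snvs_from_a_and_indels_from_b():
    a = [_rec(100), _rec(200, ref="A", alt="ACT")]  # SNV + misrouted indel
    b = [_rec(300, ref="G", alt="GTT", caller="channelB"), _rec(400, caller="channelB")]
    merged, info = merge_callers(a, b)
    assert {r.pos for r in merged} == {100, 300}
    assert info["dropped_misrouted"] == 2
    assert info["n_input"] == 4


def test_disjoint_valid_inputs_union():
    merged, _ = merge_callers([_rec(100)], [_rec(200, ref="A", alt="ACT", caller="channelB")])
    assert len(merged) == 2


def test_duplicate_key_deduplicated_keeping_channel_a():
    merged, info = merge_callers([_rec(100), _rec(100)], [])
    assert len(merged) == 1 and info["deduplicated"] == 1
    assert merged[0].caller == "channelA"


# ---------------------------------------------------------------------------
# coding annotation

# one plus- and one minus-strand gene on a hand-built sequence


def _toy():
    # gene gP: + strand, span [10, 40), exons [10,19) + [25,34) -> CDS 18 nt
    # gene gM: - strand, span [50, 80), exon [53, 71) -> CDS 18 nt
    seq = (
        "ACGTACGTAC"          # 0-9
        "GCTGCAGCT"           # 10-18 exon1 of gP: GCT GCA GCT
        "TTTTTT"              # 19-24 intron
        "AAACCCGGG"           # 25-33 exon2
        "ACGTAC"              # 34-39
        "ACGTACGTAC"          # 40-49
        "GGG"                 # 50-52
        "ATGATGATGATGATGATG"  # 53-70 exon of gM (minus strand CDS)
        "ACGTACGTA"           # 71-79
        "ACGTACGTACGTACGTACGT"
    )
    genome = ToyGenome(["c1"], {"c1": seq})
    gp = GeneModel("gP", "c1", "+", 10, 40, exons=[(10, 19), (25, 34)])
    gm = GeneModel("gM", "c1", "-", 50, 80, exons=[(53, 71)])
    return genome, [gp, gm]


def test_codon_third_position_synonymous():
    genome, genes = _toy()
    # GCT (Ala) -> GCC (Ala): position 12 (0-based), T->C
    ann = annotate_coding(_rec(pos=13, ref="T", alt="C"), genes, genome)
    assert (ann.gene_id, ann.region, ann.effect) == ("gP", "exonic", "synonymous")


def test_codon_second_position_nonsynonymous():
    genome, genes = _toy()
    # GCT (Ala) -> GTT (Val): position 11, C->T
    ann = annotate_coding(_rec(pos=12, ref="C", alt="T"), genes, genome)
    assert ann.effect == "nonsynonymous"


def test_intronic_and_intergenic_are_non_exonic():
    genome, genes = _toy()
    intron = annotate_coding(_rec(pos=21, ref="T", alt="A"), genes, genome)
    assert (intron.gene_id, intron.region, intron.effect) == ("gP", "non_exonic", "non_coding")
    inter = annotate_coding(_rec(pos=3, ref="T", alt="A"), genes, genome)
    assert inter.gene_id is None and inter.region == "non_exonic"


def test_coding_indel_is_retained_class():
    genome, genes = _toy()
    ann = annotate_coding(_rec(pos=13, ref="T", alt="TGG"), genes, genome)
    assert ann.effect == "indel_coding" and ann.region == "exonic"


def test_frame_error_and_ref_mismatch_raise():
    genome, _ = _toy()
    bad = GeneModel("gBad", "c1", "+", 10, 40, exons=[(10, 18)])  # 8 nt CDS
    with pytest.raises(AnnotationError, match="gBad"):
        annotate_coding(_rec(pos=12, ref="T", alt="C"), [bad], genome)
    genome2, genes2 = _toy()
    with pytest.raises(AnnotationError, match="reference allele"):
        annotate_coding(_rec(pos=13, ref="G", alt="C"), genes2, genome2)


def test_annotation_agrees_with_full_cds_translation_oracle():
    """Every exonic substitution in both toy transcripts classified by
    codon translation must agree with translating the whole CDS."""
    genome, genes = _toy()
    for gene in genes:
        spliced = "".join(genome.sequences[gene.chrom][s:e] for s, e in gene.exons)
        positions = [p for s, e in gene.exons for p in range(s, e)]
        for idx, pos0 in enumerate(positions):
            ref = genome.sequences[gene.chrom][pos0]
            for alt in "ACGT":
                if alt == ref:
                    continue
                ann = annotate_coding(_rec(pos=pos0 + 1, ref=ref, alt=alt), genes, genome)
                mutated = spliced[:idx] + alt + spliced[idx + 1 :]
                cds_b, cds_a = spliced, mutated
                if gene.strand == "-":
                    cds_b, cds_a = revcomp(spliced), revcomp(mutated)
                same = Seq(cds_b).translate() == Seq(cds_a).translate()
                assert ann.effect == ("synonymous" if same else "nonsynonymous")


# ---------------------------------------------------------------------------
# cascade


def _cascade_fixture():
    cfg = SimConfig(
        seed=3,
        variant_counts=VariantCounts(n_pass=5, n_low_depth=3, n_low_alt=2,
                                     n_known_snp=2, n_non_exonic=4, n_synonymous=1,
                                     n_pass_indel=0),
    )
    from pbscreen.simulate import generate_genome

    genome, genes = generate_genome(cfg)
    a, b, known, truth = simulate_somatic_variants(genome, genes, cfg)
    return genome, genes, a, b, known, truth


def test_trace_matches_manual_cascade_application():
    genome, genes, a, b, known, _ = _cascade_fixture()
    merged, info = merge_callers(a, b)
    res = apply_filters(merged, set(known), genes, genome, n_input=info["n_input"])
    assert res.trace.as_tuple() == (17, 17, 14, 12, 10, 6, 5)
    assert len(res.survivors) == 5


def test_depth_and_alt_count_thresholds():
    genome, genes = _toy()
    low_depth = _rec(pos=13, ref="T", alt="C", dp_n=19)
    low_alt = _rec(pos=12, ref="C", alt="T", ac=3)
    res = apply_filters([low_depth, low_alt], set(), genes, genome)
    assert res.trace.depth_pass == 1  # DP_normal=19 removed at depth stage
    assert res.trace.alt_count_pass == 0  # AC=3 removed at alt-count stage
    assert res.dropped["depth"] == [low_depth.key]
    assert res.dropped["alt_count"] == [low_alt.key]


def test_trace_is_order_invariant_nonincreasing_and_drops_partition():
    genome, genes, a, b, known, _ = _cascade_fixture()
    merged, info = merge_callers(a, b)
    res1 = apply_filters(merged, set(known), genes, genome, n_input=info["n_input"])
    res2 = apply_filters(list(reversed(merged)), set(known), genes, genome,
                         n_input=info["n_input"])
    assert res1.trace.as_tuple() == res2.trace.as_tuple()
    t = res1.trace.as_tuple()
    assert all(x >= y for x, y in zip(t[1:], t[2:]))  # non-increasing after merge
    all_dropped = list(itertools.chain.from_iterable(res1.dropped.values()))
    assert len(all_dropped) == len(set(all_dropped))
    assert len(all_dropped) + len(res1.survivors) == len(merged)


def test_candidate_intersection_counts_distinct_genes():
    genome, genes = _toy()
    recs = [_rec(pos=12, ref="C", alt="T"), _rec(pos=29, ref="C", alt="T")]
    res = apply_filters(recs, set(), genes, genome)
    overlap, k = candidate_intersection(res.survivors, res.annotations, {"gP", "gX"})
    assert overlap == {"gP"} and k == 1
    overlap, k = candidate_intersection(res.survivors, res.annotations, {"gZ"})
    assert (overlap, k) == (set(), 0)
    # mutation-level counting: two surviving SNVs in gP
    _, k_mut = candidate_intersection(res.survivors, res.annotations, {"gP"},
                                      count_mutations=True)
    assert k_mut == 2
    with pytest.raises(InputError, match="panel"):
        candidate_intersection(res.survivors, res.annotations, set())


def test_vcf_round_trip(tmp_path):
    records = [_rec(100, id="rs1"), _rec(200, ref="G", alt="GAT", caller="channelA")]
    path = tmp_path / "x.vcf"
    write_vcf(records, path, {"c1": 1000})
    back = read_vcf(path, "channelA")
    assert [(r.chrom, r.pos, r.ref, r.alt, r.dp_normal, r.dp_lesion, r.ac_lesion, r.id)
            for r in back] == [
        ("c1", 100, "A", "C", 50, 60, 10, "rs1"),
        ("c1", 200, "G", "GAT", 50, 60, 10, None),
    ]


def test_invariant_violation_rejected():
    with pytest.raises(InputError, match="AC_lesion"):
        _rec(ac=70, dp_l=60)
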