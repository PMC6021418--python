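# Methods

## The screen this package models

A *piggyBac* (PB) transposon plus transposase, delivered into cortical
neural progenitors, inserts semi-randomly into the genome at TTAA
tetranucleotides (with target-site duplication), disrupting genes it
lands in. Progenitors carrying a deleterious insertion produce neurons
that fail to migrate and arrest below the cortex; normal progeny reach
the cortical plate. Sequencing the insertion sites of the arrested
(ectopic) pool and subtracting genes also hit in the migrated
(cortical) pool yields candidate genes for cortical development.

Insertion sites are recovered by splinkerette PCR: genomic DNA is
digested with Sau3AI (cuts at GATC), a double-stranded adaptor is
ligated to the fragment ends, and nested PCR from the adaptor to the
transposon terminal repeat amplifies the genomic flank on each side of
the insertion. Prominent ("major") bands correspond to clonally
expanded early insertions. A companion analysis filters paired
normal/lesion exome variant calls and asks whether the mutated genes
are enriched in the candidate panel.

## Read model and parsing

A product is modelled as `adaptor + flank + transposon tag`, where the
flank runs from the insertion TTAA to the nearest GATC on that side,
and products may be observed on either strand. Parsing finds the
adaptor (the 61-nt long strand or the 48-nt short strand) at the start
of the read in either orientation, then the best 5′ or 3′ transposon
tag downstream, both by sliding-window Hamming match with a mismatch
budget of 2 (no indels — adequate for Sanger-grade substitution error
and exactly testable). Ties between equally good adaptor matches in the
two orientations are rejected (`no_adaptor`) rather than risking a flank
of uncertain orientation; among equally good tag matches the rightmost
wins, because the tag structurally terminates the product. A readable
fragment needs a flank of ≥ 20 nt with < 10% ambiguous bases;
everything else carries exactly one reject reason, and the yield summary
always sums to the input count. The PB terminal-repeat tags are
configuration (primer choice varies between labs); the defaults are
20-mers built on the canonical PB repeat `CCCTAGAAAGATA`, and are the
ones the simulator embeds.

## Mapping and site calling

Flanks are placed by a self-contained seed-and-extend ungapped mapper:
non-overlapping k-mers (k = 12 in the pipeline; any k ≥ 8) from the
query on both strands propose candidate offsets, each verified by a
full-length Hamming count. By the pigeonhole principle the mapper is
exhaustive-equivalent whenever the query holds at least
`mismatches + 1` non-overlapping seeds, which the default flank lengths
(≥ 60 nt) and budget (4) guarantee; the test suite checks exact
agreement with an all-offset, both-strand brute-force scan on random
toy genomes. Reads with two or more co-optimal placements are flagged
non-unique and excluded from site calling: in a screen a false site is
worse than a lost read.

Because the flank always reads away from the transposon, the insertion
TTAA starts at the hit end on the plus strand and ends at the hit start
on the minus strand. The implied coordinate is snapped to the nearest
indexed TTAA within 4 bp (ties to the leftmost, deterministically);
hits with no TTAA in the window are dropped and counted. Reads sharing
(chromosome, TTAA, pool) are collapsed with summed support; `major`
marks support ≥ `min_support` (default 5, emulating "major bands" —
there is no canonical value, so it is exposed as a flag). Site calling
is idempotent and invariant to read order.

## Gene assignment and accounting

A site inside a gene span is `exon` if inside any exon interval, else
`intron`. Outside all spans, the nearest gene edge within the window
(default 50,000 bp, inclusive at exactly 50 kb) assigns the gene;
5′ vs 3′ follows the gene's coding strand (upstream of the TSS = 5′).
The window is measured from the gene-span edge, not the TSS — the most
common reading of "within 50 kb" of a gene. A site inside one gene is
classified by the containing gene even when another gene's window
covers it; exact distance ties break lexicographically on gene id and
are logged. Reported percentages (near-gene over readable; exon,
intron, merged intergenic over near-gene) are rounded half-away-from-
zero to one decimal, the convention used for all accounting output;
zero denominators report 0.0 with an explicit flag.

## Candidate calling

Pools are aggregated per gene (distinct TTAA sites, max support, a
representative category with exon > intron > intergenic priority, and
`recurrent` for ≥ 2 distinct sites). Candidates are ectopic-pool genes
whose gene id does not appear in the cortical pool — gene-level
exclusion, because a tolerated insertion anywhere in a gene argues
against that gene being the arrest cause. A stricter site-level variant
(exclude only on identical TTAA sites) is available behind a flag.
Provenance always satisfies
`n_candidates + n_overlap = n_ectopic_genes`. Expression-evidence
curation is out of computational scope; the candidate table carries a
free-text `evidence` column for it.

## Somatic variant cascade

Two caller channels model a MuTect-style SNV caller and a Virmid-style
indel caller: SNVs are taken from channel A, indels from channel B,
misrouted records are dropped with a count, and duplicate keys
deduplicate with channel A precedence. The cascade then applies, in a
fixed order chosen to mirror a quality-first workflow:

1. read depth ≥ 20 in **both** normal and lesion samples,
2. alternative-read count ≥ 4 in the lesion,
3. exclusion of known SNPs by identifier list (no frequency threshold —
   the list is an input),
4. exonic variants only,
5. removal of synonymous variants.

Order affects only the per-stage counts, never the survivors. Coding
effect translates the affected codon of the toy transcript (spliced
exons, frame 0, strand-aware) before and after the substitution with
the standard genetic code; coding indels are retained as functionally
disruptive. Every dropped record lands in exactly one stage bucket, so
the trace is non-increasing and order-invariant by construction, and
the per-codon annotation is tested against a full-CDS translation
oracle.

## Enrichment and distribution statistics

Panel enrichment is the hypergeometric upper tail
P(X ≥ k | N, K, n) = Σᵢ C(K,i)·C(N−K,n−i)/C(N,n), summed in log space
(gammaln + logsumexp) for stability; it is cross-checked in tests
against exact rational enumeration and `scipy.stats.hypergeom.sf`. The
gene universe N defaults to 20,000 (of order the protein-coding gene
count of a mammalian genome) and is exposed as `--universe`. The
independent resampling route draws n genes without replacement
(Floyd's algorithm) and reports (successes + 1)/(R + 1), the add-one
correction keeping p > 0. k counts distinct overlapping genes by
default; `count_mutations=True` counts surviving variants in panel
genes instead — the two can differ substantially (with N = 20,000,
K = 2,531, n = 33 a gene-level overlap of 6 has p ≈ 0.23 against an
expectation of 4.2, while mutation-level tallies follow a different
null and are not comparable to the gene-level p).

Binned neuronal distributions are per-animal fractions over named
cortical bins (CP, IZ, VZ/SVZ, optionally WM), summing to 1 per animal.
Conditions are compared to a control with one-sided two-sample t tests
(defaults: treatment greater in VZ/SVZ and IZ, less in CP;
configurable), requiring ≥ 2 animals per group; identical zero-variance
groups are an error rather than a silent NaN. With ≥ 3 conditions a
one-way ANOVA p and Bonferroni-corrected pairwise p values can be
appended. The cell-cycle exit ratio is
(GFP⁺ BrdU⁺ Ki67⁻)/(GFP⁺ BrdU⁺).

## The synthetic-data generator

The generator emulates the *structure* of the screen, not its biology:

* **Genome/annotation** — 2 chromosomes × 400 kb, 6 genes of 3 × 300-nt
  exons separated by 1.5-kb introns, placed ≥ 2 × 50 kb apart so
  nearest-gene assignment is unambiguous (an adversarial overlapping-
  window configuration is exercised by property tests instead). A TTAA
  is planted at the centre of every exon and intron and at fixed
  offsets (1, 10, 25, 49 kb) into each flank; around every intragenic
  TTAA, GATC sites closer than 30 bp are scrubbed and one is guaranteed
  within 60–250 bp per side, so clonal insertions always produce
  readable restriction flanks (background sites get no such grooming
  and may yield short flanks, as real minor products do).
* **Insertions** — 3 driver genes (ectopic pool only), 1 shared
  passenger (both pools, same TTAA), remaining genes cortical-only;
  20 clonal reads per site (clonal expansion makes major bands deeply
  sampled), alternating 5′/3′ sides, plus support-1 background sites at
  a 0.1 minor-read rate.
* **Reads** — adaptor (long or short strand, 50/50) + flank + side tag;
  half the records emitted reverse-complemented; substitution errors at
  `base_error_rate` (0 by default; 0.01 in the error-tolerance
  acceptance run); an `unreadable_fraction` (default 0.33, emulating
  the roughly two-thirds readable yield of Sanger products) truncated
  below the readable minimum.
* **Variants** — one record class per cascade stage with controlled
  depths (pass: DP 30–90, AC 6–15; low-depth: DP_normal 5–19; low-alt:
  AC 1–3), known-SNP ids with decoys, intronic and synonymous classes
  verified by construction, and one coding indel routed to channel B.
  Pass variants are placed in driver genes so panel-intersection truth
  is known.
* **Cells** — three animals per condition, 150 cells each; control
  (CP 0.60, IZ 0.25, VZ/SVZ 0.15) vs knockdown (0.30, 0.30, 0.40).

Everything is deterministic and byte-identical under a fixed config;
truth files carry roles, insertion coordinates and variant classes
sufficient to score recovery with no other information.

What passing tests on these data do **not** show: robustness to indel
sequencing error, chimeric products, insertion-site bias, repeats or
multi-mapping at real-genome scale, diploid genotypes, transcript
isoforms, or caller-specific artefacts — the simulator has none of
those features.

## Problem sizes and runtime choices

The default simulation (800 kb genome, ~300 reads, 23 variants) runs a
full pipeline pass in a few seconds; the error-tolerance acceptance
check repeats it over 20 seeds, and the mapper/brute-force comparison
uses 100 random two-chromosome genomes of 0.8–2.5 kb with 4 queries
each — sizes chosen so the exhaustive oracles stay exact and cheap
while every code path is exercised.

## Known limitations

* The mapper is ungapped; indel-containing flanks are lost (counted,
  not misplaced).
* Adaptor detection anchors at the read start; internal adaptors
  (chimeras) are not resolved.
* One normal/lesion pair at a time; multi-patient aggregation is the
  caller's responsibility and union-vs-sum bookkeeping is explicit.
* The unreadable-read model is a flank truncation — a stand-in for
  whatever makes real products unreadable, not an inference of the
  cause.
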