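# Methods

## Detection model

A retrocopy of a multi-exon gene, absent from the reference, redirects all
of its reads to the parental locus. Two independent evidence channels
result, and the caller requires both:

1. **Exon–exon (junction-spanning) pairs.** For mates mapping into
   different exons of the parental gene, the reference template span is
   inflated by the intervening intron length. A pair is junction-spanning
   when both mates midpoint-localize to different exons and the outer span
   exceeds `insert_mean + k·insert_sd`. The default `k = 4` puts the
   threshold at 600 bp for a 400 ± 50 bp library — far above library noise
   (4 SD ≈ 3×10⁻⁵ two-sided tail) yet below any intron the default gene
   model contains (645 and 1208 bp). `k` is configurable for libraries with
   heavier insert-size tails.
2. **Trans-mate pairs.** Exactly one mate overlaps the gene region and the
   other maps on another chromosome or beyond a `trans_radius` of 10 kb.
   The radius excludes local structural noise (tandem events, reference
   artifacts) near the gene; it intentionally exceeds the span any
   concordant fragment can reach.

Split reads soft-clipped within 2 bp of an exon boundary, whose clipped
bases (≥ 12 bp, exact match) reproduce the adjacent exon's proximal
sequence, add one unit of junction support each; pairs already counted as
junction-spanning are excluded so no fragment is counted twice. The 12 bp
floor keeps the chance of a spurious exact match per read below 4⁻¹² ≈
6×10⁻⁸.

Outside mates are clustered by single linkage with window
`insert_mean + 4·insert_sd`: mates from one insertion are separated by at
most about one fragment length, so chain linkage cannot split a true locus
at 20× coverage, while two insertions a few kb apart remain distinct.
Calling thresholds: ≥ 2 trans pairs → CANDIDATE; ≥ 3 trans pairs and ≥ 3
junction-support units → CONFIDENT; a cluster overlapping an annotated
reference retrocopy fragment → FRAGMENT (known partial copies in the
reference attract 3′-end discordance without being novel insertions).
The 2/3 split deliberately places a two-read signal below the confident
tier: isolated discordant pairs warrant follow-up, not a call. Raising
`min_trans` can only remove confident calls (monotonicity, tested).

Orientation is inferred from strand concordance of the two mates of each
trans pair: for a sense insertion (same reference orientation as the
parental transcript) gene-side and outside mates map to opposite strands;
for an antisense insertion, the same strand. An 80% consensus is required;
ties report `unknown` rather than an arbitrary strand.

## Breakpoint characterization

* **TSD.** The TSD is the longest string that is simultaneously a suffix of
  the 5′ junction context and a prefix of the 3′ junction context, searched
  from 30 bp down to 6 bp. Below 6 bp an anchored duplication is
  indistinguishable from chance in a ~30 bp window (expected count ≈ 1 at
  4⁻⁶ per trial); the observed canid FGF4 range is 11–17 bp. With
  `max_mismatch > 0` the longest duplication within the mismatch budget is
  returned, preferring exact matches at equal length. An exhaustive
  all-substring-pairs oracle (`tsd_brute_force`) verifies the anchored
  search on random planted junctions.
* **G/C window.** Defined as exactly the flank5 + TSD + flank3 string with
  10 bp flanks, percentage rounded half-up to one decimal. This definition
  reproduces all seven published canid FGF4 site values (e.g. 12/33 = 36.4%
  at FGF4L1) and is treated as normative. Non-ACGT symbols are rejected
  rather than weighted.
* **Motif.** `TTAAAA` is scanned on the reference forward strand of the
  window by default — site windows are reported forward-strand regardless
  of retrocopy orientation, and the published scan behaves the same way;
  both-strand scanning is an explicit flag and reported separately.
  Overlapping occurrences are all reported.
* **ECR proximity.** Conserved elements (an input BED; conservation is
  never recomputed) overlapping ± 2.5 kb of the site midpoint by at least
  one base are counted.
* **Truncation.** End-free global alignment of the (polyA-stripped,
  mRNA-oriented) retrocopy to the parental mRNA (match 1, mismatch −2, gap
  open −5, extend −1); `trunc5`/`trunc3` are the unaligned mRNA termini.
  `orf_intact` requires full ORF coverage, retained frame (net in-ORF indel
  length divisible by 3) and no premature stop. Inputs below 90% aligned
  identity are rejected as not being a retrocopy of the gene. A retrocopy
  whose 3′ junction base is adenosine is inherently ambiguous against the
  polyA tail; the polyA stripper may absorb at most that terminal base,
  shifting `trunc3` by one.

## Variant classification

Differences called from the same end-free alignment are represented
VCF-style (anchored indels), left-normalized against homopolymer context so
population-VCF lookup is well-defined, and projected to genomic coordinates
through the exon map. Classification requires allele identity at the
projected position — positional overlap with a different allele does not
count as shared. Records failing FILTER mark their positions `UNKNOWN`;
multiallelic records are split. Haplotype matching scores each phased
parental haplotype by allele mismatches over the table's positions and
returns all tied minima; a table not covering every called variant returns
`UNKNOWN` with a warning rather than a guess.

## Genotyping arithmetic

Insertion allele frequency is `(het + 2·hom)/(2n)` from called copy numbers
0/1/2 (no genotyping-error model; assay results are taken as reported).
Intervals are Wilson score at 95% — small cohorts (n = 5–30) dominate breed
panels and the Wald interval degenerates there. Exon–exon amplicon sizing
is pure coordinate arithmetic: the genomic product exceeds the spliced
product by exactly the summed skipped-intron length; primers in one exon
are rejected because the assay cannot discriminate. In-silico product
prediction uses exact primer matching only — thermodynamics and primer
design are out of scope.

## Synthetic data

`synthio` emulates the data structure the detector assumes rather than a
sequencing instrument. Defaults: two 200 kb chromosomes; one three-exon
gene (exons 476/104/2620 bp, introns 1208/645 bp) giving a 3.2 kb mRNA with
a translatable 621 bp ORF spanning all exons between real UTRs; reads
100 bp, fragments 400 ± 50 bp, 20× coverage, 10⁻³ uniform substitution
errors, no indel errors (detection uses pair geometry, not base accuracy).
Library insert statistics are asserted defaults, not derived from any
particular instrument. Insertions place the oriented, optionally truncated,
polyA-tailed mRNA after the target position followed by a second copy of
the target-site bases, so `… TSD | insert | TSD …` is exact by
construction.

Alignments are derived by projecting each read's coordinates through the
insertion map: contiguously projectable runs merge, the longest run (≥ 20
bp) becomes the placement, the remainder is soft-clipped; polyA-derived
bases are unmappable (reads mostly inside the tail are emitted unmapped,
never placed elsewhere). This is deterministic, dependency-free, and
produces standard SAM, which the detector consumes exactly as it would an
aligner's output. What the simulator does **not** model — mapping
ambiguity, repeat-induced mismapping, base-quality-correlated errors, PCR
duplicates, reference mis-assembly — bounds what the recovery tests show:
they validate the detection logic and its thresholds under clean mapping,
not robustness to real-genome mapping artifacts.

Coordinates are 1-based inclusive everywhere inside the package; the I/O
adapters convert to BED/SAM conventions at the boundary, and a fuzz test
checks the round trip.

## Problem sizes

The recovery suite runs 20 seeded simulations with 1–2 planted insertions
(TSD 11–17 bp, random strand, 5′ truncation up to 120 bp) plus 20 matched
insertion-free controls on compact 2 × 60 kb genomes at 20× coverage —
about 12,000 read pairs per replicate, chosen so the full suite completes
in about a minute while every detection code path (both evidence channels,
clustering, both-signals rule, orientation) is exercised. The pipeline demo
uses 2 × 120 kb. Scaling is linear in genome size × coverage.

## Known limitations

* Single-locus per scan: genome-wide all-gene screening is an outer loop,
  not built in; reference retrocopy cataloguing is likewise out of scope.
* Junction recovery from a sequenced insertion amplicon
  (`cli_io.locate_insert`) walks the longest common prefix/suffix against
  the empty-site reference; chance identity at a junction can shift a
  boundary by a base or two (expected ≈ 0.33 bp per junction).
* The TSD finder assumes breakpoint-accurate junction contexts; it does not
  assemble junctions from reads.
* Insertion dating and parental-haplotype phylogenetics are out of scope.
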