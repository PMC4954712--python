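# Methods

## The event model

The package models a *direct interchromosomal insertion*: a donor
segment D = [s, e] from one chromosome copied into an acceptor
chromosome directly after position B, without loss of acceptor sequence
other than small junction-adjacent edits. The derivative chromosome is

```
acc[1..B] + donor[s..e](orientation o) + micro-insert + inverted acc[B+1..B+k] + acc[B+k+1..] (with SNVs/deletions)
```

with the junction micro-architecture typical of replicative repair
(MMBIR/FoSTeS): microhomology of h bases shared by the acceptor end and
donor start; an optional short foreign fragment at the distal junction
whose first `ov` bases also match the donor end (so only
`length - ov` novel bases appear physically); a k-bp inversion of the
acceptor bases immediately distal to the break; and isolated
junction-adjacent substitutions and deletions. The haplotype length
follows `len(acc) + len(D) + (insert_len - ov) - deletions`; the
microhomology bases are present once in each source reference, and both
boundary designations use the maximal-extension convention (acceptor
extended right to B, donor extended left to s), matching how such
junctions are reported: ambiguity is expressed as the microhomology
length, not hidden in coordinates.

Coordinates are 1-based inclusive everywhere; each contig carries an
`offset` so small in-memory contigs present genome-scale positions
(local base i has genome coordinate offset + i). Conversion to 0-based
half-open happens only at BED export.

## What the generator emulates — and what it does not

`synthetic_data` produces: random reference contigs (default 200 kb
acceptor, 200 kb donor, 5 kb third donor); the mutant haplotype with a
full segment map back to reference coordinates; error-free
forward-reverse paired-end reads (default 2x101 bp, fragment
N(350, 35) so that twice the mean equals the 700 bp discordance
threshold; coverage is per haplotype copy); exact truth projection to
SAM (full-match CIGARs inside segments, soft-clipped primary +
supplementary records across junctions, MAPQ 60); X-linked cohorts; and
long-format Ct tables (3 extractions x 3 technical replicates,
4-decimal Ct precision).

It does **not** emulate sequencing errors or base-quality structure
(an optional uniform substitution rate exists but defaults to 0), SNP
background, GC bias, duplicates, or repeat-mosaic reference sequence.
Passing tests therefore demonstrate correctness of the *logic* —
detection predicates, clustering, segmentation, assay arithmetic — under
clean data, not robustness to real-data noise. The exact-match primitives
(the internal mapper, clipped-sequence remapping, primer binding) are
explicitly desk-scale stand-ins and would need mismatch tolerance on
real reads.

### Identifiability edits

A planted junction must also be *readable*: with short features (a 2 bp
microhomology, a 9 bp novel insert tail, a 12 bp inversion) a single
chance base match at a boundary changes the maximal-parsimony parse of
the junction sequence (for example, the base after the donor end
matching the first novel insert base extends the donor anchor by one).
`plant_junction` therefore adjusts single reference bases flanking each
planted feature — after writing the shared microhomology/overlap bases —
until the planted parameters are the unique maximal parse: anchor stops
(the base after the acceptor break must differ from the first donor
base, etc.), exact microhomology and overlap scans, exact inversion
scan, and the base preceding the micro-insert fragment on its source
contig. This is a fixed-point loop with a convergence guard; real
reported junctions satisfy these conditions implicitly, since otherwise
the published coordinates could not have been stated.

The preset also plants a 180 bp palindrome (88 bp arms, TATC hairpin
loop) across the acceptor breakpoint, reflecting the inverted-repeat
context in which these Xq27.1 insertions recur. A perfect palindrome
centered near the breakpoints makes the 12 bp inversion parse genuinely
ambiguous — the inverted segment is then nearly identical to the forward
reference — so the identifiability edits puncture the palindrome near
its center and the preset's palindrome is imperfect, much as the real
locus sequence is interrupted around the breakpoint region. Palindrome
annotation itself is exercised on clean constructed hairpins.

## Detection

* `find_discordant_pairs`: high-quality pairs only (both mates primary,
  non-duplicate, MAPQ >= 20 — the cut-off is a documented choice, not a
  published value); flagged when mates map to different contigs or the
  insert is strictly greater than the threshold (default 700 bp).
* `cluster_discordant`: sliding windows (200 bp default, step =
  window/2), minimum support 3, merge of overlapping qualifying windows
  sharing a partner contig; the peak is the per-base position with the
  highest count of junction-facing read boundaries (read end for
  forward, start for reverse), leftmost on ties. Clusters intersecting
  poor-alignment regions (windows with > 50% low-MAPQ records) are
  dropped. Window step, merging, support, and tie-breaks are
  unspecified in the source protocol; these defaults are configurable.
* `find_split_reads`: soft clips of >= 20 bp whose clipped sequence maps
  away from the anchor (another contig or > 1 kb). The clipped locus is
  resolved in order of preference: the read's supplementary alignment, a
  unique whole-clip exact match, then the longest uniquely matching clip
  prefix/suffix — necessary because distal-junction clips are composites
  (micro-insert + inversion + acceptor) that never match whole. The
  breakpoint position is the anchor's last aligned base in every case.

## Junction resolution

Per split cluster (anchored contig, position, clip side; support >= 2) a
positional-majority consensus is built with reads aligned on the shared
clip boundary; ties at more than 10% of columns flag low confidence.

Segmentation anchors the consensus ends with their maximal exact
reference matches (both strands, all contigs; ties broken by contig
order, then forward strand, then leftmost, and recorded as ambiguity —
the forward-strand preference resolves mirror artifacts inside inverted
repeats). A pure greedy left-to-right walk with `min_match` 10 was
rejected: over ~400 kb of reference (both strands) a spurious exact
10-mer is expected at most positions, so short features would routinely
be mis-tiled. Instead the short gap between the long anchors is
explained structurally, right to left:

1. **variant window** — a gap suffix may be acceptor sequence carrying
   isolated edits; candidate extensions (>= 8 bp, edit fraction
   <= 25%, score = length - 4 x edits) are aligned right-anchored with
   edlib and the SNVs/deletions read off the alignment path;
2. **inversion** — the maximal k with the gap suffix equal to the
   reverse complement of the acceptor bases immediately left of the
   resume point (only an abutting minus-strand match is called);
3. **micro-insert** — the remaining gap is searched with leftward
   extension into the donor tail, longest extension first; the unique
   hit gives source, total length and the donor overlap (reported as
   overlap, not assigned to either source); no unique hit of >= 10 bp
   leaves an unknown-origin fragment.

Both hypotheses — with and without the variant window — are evaluated
and the one leaving fewer unexplained bases wins (ties to the simpler).
Each resolved junction is canonicalized so the acceptor flank reads
forward, then classified: acceptor->donor is the proximal side,
donor->acceptor the distal side; the best-supported consensus per side
feeds the final call. Microhomology between adjacent segments is the
maximal k with the left segment's last k reference bases equal to the
right segment's first k (deterministic, symmetric under
reverse-complement role swap).

The final call reports the insertion point as "between B and B+1",
inserted length = donor length + net micro-insert - junction deletions,
four mate-paired VCF 4.2 breakend records (junction-inserted bases
carried in the ALT strings; local contig coordinates so records validate
against the header) plus one symbolic INS record, and the
derivative-chromosome notation with band labels taken from
configuration, not computed.

`annotate_palindrome` finds the maximal inverted repeat (loop <= 8 bp,
arms >= 20 bp, perfect arm match) whose span contains the breakpoint and
reports arm length, loop bases, and breakpoint distance to the loop
midpoint.

## Depth and copy gain

Depth counts aligned reference-consuming bases (CIGAR M/=/X, not D) in
1 kb windows (window size is a package choice); region summaries use the
windows fully contained in each region with sample SD across windows.
The copy-gain fold is the insert-region mean over the mean of the flank
means; the gain threshold 1.35 is the midpoint between no gain (1.0) and
the trisomy expectation (1.5). With per-copy coverage c, flanks sit at
2c and the inserted region at 3c.

## Genotyping

Published primer genomic coordinates are not available, so primer sites
are solved exactly from the published product sizes (340/595/235 bp;
21 nt primers) on the synthetic genome — wild-type F/R centered on the
insertion point, donor-internal primers solved from the junction-product
length equations through the mutant-haplotype coordinate map — then
verified by in-silico PCR (exact-match binding, convergent orientation,
product = inclusive distance between outermost 5' ends, maximum product
2 kb). Genotype is a pure function of sex and the amplicon span set;
anything outside the three legend rows is `inconsistent`. Segregation
checks concordance under X-linkage (affected males carry; unaffected
males do not; carrier females are asymptomatic) and audits parent-child
links for father-to-son transmission; panel accounting is
2 x females + males X chromosomes.

## Comparative Ct

Aggregation order (a documented choice): technical replicates are
averaged within extraction; dCt per extraction = Ct(target) -
Ct(housekeeping); ddCt subtracts the calibrator's mean dCt; fold =
2^-ddCt with amplification efficiency fixed at 2. The point estimate
uses the mean dCt (so the calibrator's fold is exactly 1); the SD and
the two-sample t test (Student by default, Welch by flag) use
extraction-level folds — the test is on folds rather than dCt values, a
documented choice. A sample/gene with every well undetermined is
reported "not detected", never 0 or infinity; extractions mixing
undetermined and numeric wells are dropped with a warning.

## Problem sizes and numerical choices

Defaults throughout: read length 101, fragment 350 +/- 35, insert
threshold 700, window 200, min support 3, min clip 20, `min_match` 10,
MAPQ cut-off 20, window size 1 kb, gain threshold 1.35, primer length
21, max product 2000, efficiency 2. All are keyword arguments.

Test-suite problem sizes are chosen to keep the full suite under a
minute of compute while leaving the statistics meaningful: the preset
pipeline runs once at 40x over the full 200 kb contigs (~110k reads);
the randomized recovery property runs 100 independent junction specs at
40x on 6 kb/3 kb/1.5 kb mini-genomes; mapper/projection equivalence uses
three random 20 kb + 10 kb references; the transmission audit walks 300
random two-generation families; trisomic depth uses a 20 kb/16 kb
genome. The randomized recovery suite draws microhomology 0-6,
inversion 0-15, and micro-insert length in {0} or [12, 25] with donor
overlap 0-10: a planted overlapping insert much shorter than the 10 bp
unique-hit floor cannot be attributed to a source from sequence even in
principle, so shorter inserts are out of the identifiable regime by
construction.

## Known limitations

Exact-match primitives throughout (mapper, clip remapping, primer
binding) assume error-free reads; no mismatch-tolerant binding,
duplicate marking, GC correction, or segmentation algorithms (CBS/HMM)
are provided. Only one insertion event per genome is modelled; nested or
multi-donor events raise composite-event errors rather than being
resolved. The palindrome annotator requires perfect arms; near-perfect
inverted repeats report only their longest perfect core.
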