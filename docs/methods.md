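# Methods

`dmrecon` reconstructs the circular structure of highly amplified
extrachromosomal DNA elements ("double minutes", DMs) from short-read
tumor/normal whole-genome sequencing, estimates how many copies of each
circle a tumor cell carries, validates candidate circles with linked-read
barcode sharing, and compares the circle population between two time
points of the same tumor.  This note describes the model behind each
stage, the parameters that matter, what the bundled simulator does and
does not emulate, and the numerical choices taken where the design was
genuinely open.

## 1. Amplified-segment selection

Input is a per-segment copy-number table (`chrom start end log2R`)
produced by any coverage segmenter; segmentation itself is out of scope.
log2R is the log2 tumor/normal coverage ratio.  DM segments sit in the far
right tail of the per-sample log2R distribution, so selection keeps
segments with `log2R > cutoff`, where the cutoff is either explicit or
`'auto'` = mean + 2·sd over all input segments.  The tail rule is applied
genome-wide, not per chromosome.  Auto mode refuses degenerate (zero-sd)
distributions rather than guessing.  `compute_segment_log2r` can fill the
log2R column from two alignment sets (mean reference-consuming depth,
pseudocount 0.5); it exists so simulated data round-trip without an
external segmenter and is not a change-point method.

Two amplified segments whose reference gap is at most `adjacency_max_gap`
(default 10 bp; segmenters usually emit abutting intervals) form an
*adjacent* pair — one contiguous amplified run that the segmenter split on
a coverage step.  Manual boundary curation is supported only as an
explicit override table, never silently.

## 2. Junction evidence at segment boundaries

Each segment has a 5' (L) and a 3' (R) boundary.  Reads overlapping the
±`boundary_flank` (50 bp) window of a boundary are examined for three
evidence classes:

* **Soft-clipped reads.**  A clip of ≥ `min_clip_match` (20) bases is
  placed against the ±`search_flank` (1 kb) reference flank of every other
  boundary, both strands.  Placement is seed-and-extend: an exact 14-mer
  from either end or the middle of the clip must occur in the flank before
  a local alignment (match +1, mismatch −2, gap open −3, extend −1) is
  attempted; qualifying hits need ≥ 95% identity over ≥ 20 bases.  The
  placement must be unique: placements at the same genomic location seen
  through several overlapping flank windows collapse to the boundary
  nearest the junction-adjacent hit edge, and distinct locations must be
  separated by a score factor of `uniqueness_ratio` (1.2).  The clip side
  gives the anchored boundary's side (3' clip → R, 5' clip → L); the hit
  strand gives the partner side; breakpoints are the last aligned base and
  the hit edge, exact at base resolution.
* **Discordant pairs.**  A flank read whose mate maps to another
  chromosome or ≥ `discordant_min_distance` (800 bp) away contributes when
  the mate falls within `search_flank` of another boundary.  Sides come
  from the strands (a read on + points rightward into a junction → R side;
  − → L), which is the FLAG-based orientation rule.  Templates are
  deduplicated by read name, so a pair seen from both of its boundaries
  counts once.  A pair whose both ends sit in the same boundary's flank is
  ignored (self-pairs carry no junction information).
* **Bridging discordant reads.**  When the sequence joining two boundaries
  is itself absent from the local flanks (repetitive or unrepresented),
  junction clips place nowhere and mates fall outside every boundary
  flank.  Those orphan mates are clustered per boundary (same chromosome,
  positional gap ≤ 2 kb, majority strand).  Two boundaries bridge when
  their clusters lie on one chromosome within `bridge_max_distance`
  (10 kb) of each other, on opposite strands pointing away from the
  interval between them — the configuration a single intervening fragment
  a→fragment→b produces.  The count is the smaller cluster size and the
  breakpoints stay unresolved.

The orientation class of a junction follows from the side pair alone:
R–L = head-to-tail (→→), L–L = tail-to-tail (←→), R–R = head-to-head
(→←).  Evidence is aggregated per (unordered boundary pair, orientation);
a junction needs `min_sv_support` (2) total templates.  The per-junction
supporting-read dump replaces by-eye curation of alignments with a
machine-readable review file.

Cross-sample search (`search_breakpoints_in_sample`) re-counts support for
*given* junctions in another sample (relapse junctions in the diagnosis
sample, or either tumor's junctions in the germline).  Uniqueness against
all boundaries is deliberately not required there: the junction is known,
the question is only whether reads for it exist, so even single-read
support registers as "present".

## 3. Boundary graph and cycle enumeration

The breakpoint graph has one node per boundary (2 per segment) and three
bidirected edge types: the segment edge (L–R of one segment), sv edges,
and adjacent edges (iR–jL of an adjacent pair).  A circular amplicon is a
simple cycle alternating segment edges with junction edges — entering
every segment at one boundary and leaving at the other, in either strand
orientation.

Enumeration uses Johnson's simple-cycle algorithm (networkx) on a directed
expansion in which every bidirected edge becomes an intermediate
edge-token node with arcs both ways.  Node-simplicity of the expansion
enforces both node- and edge-distinctness, excludes the out-and-back
two-step walk over a single edge, and reports each undirected cycle
exactly once per traversal direction — so the raw list always has even
length, one direction is dropped by canonical deduplication
(lexicographically minimal rotation over both directions), and cycles that
use only one boundary of some segment are removed by the alternation
filter.  The alternation predicate implies, and slightly strengthens, the
single-boundary removal rule; the test suite proves the whole chain equal
to a brute-force enumeration of alternating closed walks on random graphs
with up to 8 segments.  Cycles may not reuse a segment (simple-cycle
semantics), so a tandem duplication inside one circle is not
representable; this is a known limitation.  An explosion guard
(`max_candidates`) aborts with a clear error instead of exhausting memory
on pathological evidence sets.  Reported structures are named in order of
decreasing total length, with segment tours written `seg3+->seg5-...`.

## 4. Copy number from SNV allele ratios

A heterozygous germline SNV on an amplified segment had VAF 0.5 before
amplification.  If the amplified haplotype carries the alternative allele,
the tumor allele counts approach alt:ref = C:1 for an amplicon at C copies
per cell, so the median alt/ref count ratio over such SNVs (the VAF > 0.5
"upper branch"; exact 0.5 ties are excluded) estimates C.  SNVs below
`min_snv_depth` (10) reads or with zero reference reads are excluded; the
median's 50% breakdown point makes the estimate robust to a minority of
misassigned or low-quality sites.  Tumor purity and the single chromosomal
copy of the amplified haplotype are deliberately ignored, which biases C
upward by roughly one copy at high amplification and more at low; the
estimator is intended for the strongly amplified regime (C ≫ 2).
Estimation uses only segments unique to one structure.  A segment shared
by k structures estimates the *sum* of their copy numbers;
`shared_segment_subtraction` subtracts known co-occupants (clamping at
zero), and `fraction_by_subsegment_presence` converts the copy number of
an optionally-carried sub-segment into the percentage of carrier circles,
`(cn_with_feature − cn_other)/cn_total`.

Two-time-point comparison intersects SNV tables on (chrom, pos, ref, alt)
and flags pairs whose VAF moves from ≤ 0.10 in one sample to ≥ 0.90 in the
other (both directions, labeled).  The exemplar shift is 0.02 → 0.96; the
0.10/0.90 defaults are our formalization since no published cutoff exists.
At coverage below roughly 20× an unamplified heterozygous site can
occasionally fluctuate past these thresholds, so the depth filter should
be kept on when comparing shallow samples.

## 5. Linked-read validation

Reads sharing a barcode derive from one long input molecule.  For a
claimed junction, windows of up to `link_window` (10 kb; 8 kb in the
bundled fixtures) are taken *inside* each segment adjacent to the joined
boundaries, binned at `link_bin_size` (1 kb), and the number of distinct
shared barcodes is counted per bin pair.  With coordinates increasing
along both axes, a real junction concentrates sharing in the corner
adjacent to the two joined boundaries: anti-diagonal corners for
head-to-tail, lower-left for tail-to-tail, upper-right for head-to-head.

The published call was visual; here *supported* requires (i) a bin pair
with ≥ `corner_min_barcodes` (10) shared barcodes inside the expected
corner and (ii) corner-quadrant mean enrichment ≥ `corner_fold` (5×) over
the diagonally opposite quadrant — the corner the reverse orientation
would light up.  Windows narrower than 4 bins cannot discriminate corners
(molecules span the whole small segment and light the whole matrix), so
the verdict there rests on the corner count alone.  Barcodes are treated
as molecule proxies; no molecule reconstruction or phasing is attempted.

A whole cycle is validated junction by junction; additionally every
skip triple (A, skip B, C) with B shorter than the average molecule
length is tested for direct A–C sharing (molecules spanning B), longer
B being untestable.  The cycle is *invalidated* if any junction fails,
*validated* if all junctions and all testable skips pass, otherwise
*inconclusive*.  This is how a cycle that is graph-theoretically valid but
stitched from junctions of different co-existing circles is rejected: its
borrowed junctions pass individually, but the adjacency it needs shows
only background-level sharing.

## 6. The simulator

The simulator is first-class, tested code that generates every input the
pipeline consumes, with complete ground truth: a random reference
(100–320 kb), planted circles (ordered, oriented segments), pre-aligned
paired-end reads, SNV tables, and barcode-tagged linked reads.  Reads are
emitted with computed CIGARs, positions, strands and mate fields rather
than run through an external aligner, keeping tests hermetic; junction
reads carry the correct soft clips, junction-straddling pairs become
discordant records, and a *bridged* junction splices in a copy of a
distal reference region (≥ 1 kb from every boundary) so that clips are
untraceable against boundary flanks while mates map into the distal
source — exactly the bridging configuration.  A random, truly unmappable
gap could not produce bridging evidence at all (its mates would be
unmapped), which is why the gap is modeled as displaced real sequence,
matching the interpretation of such junctions as short fragments mapped
elsewhere.

Geometry and depths are the study conditions at desk scale, linearly
shrunk to keep test runtimes in seconds: segments 3–20 kb (study: tens of
kb), circles 24–44 kb (study: 403–974 kb), tumor/normal depth 12–30×
(study: 57×/36×), molecules of exponential length, mean 4 kb truncated at
twice the mean (study: 26–31 kb), so the molecule:structure ratio (~0.1)
and molecule:window ratio are preserved.  Binomial SNV counts use
alt:ref = C:1 on the upper branch, mirroring the estimator's model, with
segment depth scaled by (2+C)/2.  Sequencing error is off: the junction
evidence thresholds are count-based, not quality-based, and an error
model would only dilute the seed prefilter, a sensitivity knob that can
be studied separately.  Consequently the suite demonstrates correctness
of the logic under clean mappings — not robustness to mapping artifacts,
repeats, GC bias or purity, which real data have and the simulator does
not.

Bundled fixtures: `tiny` (one 2-segment circle), `bridging` (one bridged
junction), `relapse_like` (five circles, CN 5–20, sharing two segments,
one adjacent pair, one short segment for skip testing), `invalid_cycle`
(two circles sharing a segment whose evidence admits a third, false cycle
over a reference adjacency), and `two_timepoint` (a conserved circle with
four planted VAF-shift SNVs plus circles private to each time point).
All outputs are byte-deterministic for a fixed seed.

## 7. Numerical and interface choices

* All internal coordinates are 1-based inclusive (SAM convention); BED
  input is shifted at the reader behind an explicit dialect flag.
* All report writers order rows deterministically so outputs diff cleanly.
* Window parameters are per-sample adjustable because the operating point
  is known to vary between cohorts (e.g. wider flanks for noisier
  libraries).
* Power at the defaults: a junction at C copies and haploid depth d
  yields ≈ C·d·(L−2·min_clip)/L soft-clip supporters (read length L), and
  its expected linked-read corner count is ≈ molecule coverage ×
  exp(−d_bin/λ) for bin distance d_bin and molecule mean λ; fixture
  parameters were chosen so that true junctions sit several-fold above
  `corner_min_barcodes` and background adjacencies sit below it.
* Selection among surviving candidate cycles (the study hand-picked a
  covering set) is not automated; the report lists all validated cycles
  and a user chooses, keeping the heuristic out of the measurement path.

## 8. Known limitations

Circular ecDNA cannot be distinguished from chromosomally integrated
tandem amplification (HSR) from short reads alone; structures are
reported as cycles, not as a cytogenetic claim.  Junctions whose partner
sequence is longer than the insert size and absent near any boundary are
recoverable only as bridging candidates or by linked reads.  The copy
number model ignores purity and subclonal structure.  Segment reuse
within one circle is not representable.
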