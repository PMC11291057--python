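# Methods

## Locus model and coordinates

All coordinates are 0-based, half-open; SAM's 1-based positions are
converted at parse time.  The IGH locus is modeled as an ordered array
of J, D and V genes.  On the human reference the locus sits on the
minus strand of chromosome 14 with the J block at the lowest
coordinates, then D, then V; the toy locus reproduces this geometry
(all genes on '-'), and the model validates RSS placement
strand-awarely: a gene's 5' RSS lies upstream of its start *on its own
strand*, the 3' RSS downstream.  Recombination-facing RSSs are required
per class — V genes carry a 3' RSS, J genes a 5' RSS, D genes both.

An RSS is stored as a single representative coordinate: the heptamer
edge adjacent to the gene, numerically the gene boundary itself.  The
biological anchor (heptamer start vs end) is not standardized in
distance reporting; fixing one anchor and absorbing the ambiguity in
the 50 bp tolerance is the documented choice.

`jd_interval` — leftmost J start to rightmost D end — is the region
reads must touch to be profiled.  Recombination always removes sequence
between a J and a D (and possibly beyond), so every informative read
overlaps this span, while reads split by structural variation inside
the V locus do not and are excluded by construction.

## Junction detection and confidence

Per read, primary and supplementary alignment records are merged and
sorted by read coordinate.  Each adjacent segment pair yields a
junction; each side is attributed to the nearest RSS of any gene (ties
broken toward the smaller gene start, then the 5' side).  A split
junction is **confident** iff both anchor distances are ≤ 50 bp
(inclusive — "within 50 bp" is read as ≤).

Long deletions (≥ 100 bp, configurable) inside one segment are scanned
from the CIGAR.  When a deletion's two edges anchor to two distinct D
genes, the repetitive D locus lets aligners slide the gap, so the
anchor rule is replaced by a length rule: confident iff
|deletion length − d| ≤ 50, where d is the germline distance between
the two genes' *facing* RSS anchors (the high-coordinate anchor of the
left gene to the low-coordinate anchor of the right gene).  Deletions
not flanked by two D genes fall back to the anchor rule.  The 100 bp
floor keeps ordinary indel noise out; D-gene spacing (hundreds of bp)
motivates the value.

Junction identity is normalized to reference order (lower-coordinate
anchor first, chain sorted by anchor coordinate), which makes event
keys independent of sequencing orientation.  Identity uses gene names,
RSS sides and orientation flags only — never exact breakpoints — so
junctional non-templated nucleotides and small jitter do not fragment
events.  Junctional insertions appear as unaligned read bases between
segments and are ignored.

MAPQ filtering defaults to 0 (keep everything): somatic haplotypes may
map poorly and discarding them would bias the profile.

## Multi-reference selection

Each read may be aligned against several references (the panel
degenerates gracefully to one).  References are ranked per read by
(confident-junction count desc, total anchor distance asc, panel
priority) and the best is kept.  The published criterion ("split sites
close to RSSs on that reference") fixes only the first key; the rest is
one deterministic, documented instantiation.

## Event classification

Classes and their signatures on normalized chains:

* **canonical** — single J(5')–V(3') junction, no inversion.  The D
  gene between the two joints is ≤ 40 bp and is subsumed (soft-clipped
  or absorbed) rather than producing its own segments.
* **partial_DJ** — single J(5')–D(3') junction; the D gene's 5' flank
  continues germline.
* **partial_VD** — single D(5')–V(3') junction; the read's J side
  continues germline into the J–D intergenic region.
* **multi_D** ("RSS skipping") — chain entering the D locus at one D
  gene's 3' RSS and leaving from a different D gene's 5' RSS (as splits
  and/or confident inter-D deletions), with a J and ≥ 2 distinct D
  genes.
* **inversion_J / inversion_D** — an orientation-change junction
  joining two same-class genes (5' RSSs for J, 3' RSSs for D: the span
  between the respective RSSs of two consecutive genes is inverted in
  place).
* **inversion_V** — orientation-change junction joining a D gene's 5'
  RSS to an inverted V 3' flank (the V's 3' RSS).
* **double_VD** — ≥ 2 V–D junctions entering consecutive D genes via
  the 3' RSS of one and the 5' RSS of the other, with no J gene
  anywhere in the chain.  This pattern is figure-encoded in the
  literature rather than textually specified; the simulator realizes it
  as an inverted V attached at the left D's 3' RSS plus a normal V–D
  joint at the right D's 5' RSS, and the classifier keys only on the
  invariant part (two V–D junctions, consecutive D RSSs, no J).
  Precedence: same-class inversions, then double_VD, then inversion_V
  (whose D anchor must be the 5' RSS, so the two cannot collide).

Anything else is **unclassified**.  Chains truncated by read ends
classify as what the visible junctions support (a multi-D read too
short to reach the V side is indistinguishable from a partial D–J
joint; this overcount is inherent to read-length-limited evidence).

## Event grouping, clonality, gene usage

Reads with identical normalized chains merge into one event.  A read is
confident evidence when *all* its junctions are confident; an event is
confident when at least one supporting read is.  Simpson's index
SI = Σn²/N² and its denominator N use reads of confident events only —
the same evidence base as gene usage (the source analyses are silent on
whether unconfident reads enter N; using confident evidence throughout
keeps clonality and usage consistent).  Clonality: SI > 0.25
monoclonal, SI < 0.125 polyclonal, otherwise in-between; both
thresholds strict, so the boundary values are in-between.

Gene usage counts each event once per sample: canonical events
increment the (J, V) matrix; all other events increment (J, D) with the
chain's first D–J pair.  Events without a J–D pair (pure inversions,
double V–D, partial V–D) contribute to neither matrix.

## Assembly profiling

Gene-to-contig alignment uses edlib's infix (semi-global) mode on both
strands over all database alleles of a gene; the best location is
reported with its edit distance as the mismatch count, the interval is
masked and the search repeated so multi-copy genes are all found.  Hits
worse than 15% of gene length are not reported at all — this reporting
cutoff is deliberately separate from the 15-*mismatch* orphon rule,
which flags likely orphons/non-functional copies among reported hits
(> 15 orphon-like; = 15 kept).  A contig whose every hit is orphon-like
is dropped from downstream analysis.

Duplicate naming: for the sequence-identical pairs (IGHV3-23/-23D,
IGHV1-69/-69D, IGHV2-70/-70D), when several instances occur on one
contig the copy first in locus order keeps the base name and later
copies get "D", "D2", ... .  The contig's locus direction is inferred
from the germline ranks of its hits.

V(D)J breakpoints: adjacent different-class hits within 10 kb flag a
somatic joint *provided germline genes are missing between them* — the
germline J-to-D adjacency itself sits within 10 kb and must not be
flagged.  This skipped-gene condition is a necessary refinement of the
bare distance rule.  Contig-end breakpoints: retained contigs are
ordered by median germline rank (ties: longer first); contigs with
internally conflicting gene order are reported unplaceable; each
adjacent pair is classified disjoint / overlap / duplication from its
gene sets, with the facing boundary genes recorded.

The inventory counts V genes excluding pseudogenes (functionality taken
from the germline table), all D and J genes, per contig and for the
longest contig, plus the germline genes missing from the assembly.

## Preprocessing for reassembly

Reads are cut at the read coordinates of qualifying junctions —
confident junctions of any class *except* V–V adjacencies (potential
germline SVs) — into `{id}/part{i}` pieces that exactly partition the
read.  When junctional insertions or microhomology leave a gap or
overlap between the two segments' read intervals, the cut lands at the
midpoint of the inter-segment span, guaranteeing a partition.
Unconfident junctions never cut.  Somatic hypermutations are never
corrected: they do not affect assembly structure, and correcting them
risks erasing real polymorphism.

Every processed read overlapping the J–D interval (any overlap by
default; a minimum-fraction rule is available) is then duplicated
exactly once (`{id}/dup`), doubling depth over the interval.  Re-running
enrichment is refused via the duplicate-name guard.

## SV genotyping, reconciliation, reference stitching

The bundled catalog mirrors the seven common IGH SVs (six deletions and
the complex IGHV3-64D/IGHV5-10-1 vs IGHV1-8/IGHV3-9 region); anchor
genes are the nearest flanking genes outside each region.  Calls follow
the flank/interior logic described in the README; note the rule is not
monotone in hit content in general — interior evidence added to a
contig previously called "deleted" flips it to "present", which is the
intended biology, while added *coverage* moves "unknown" to a
determinate call.

Reconciliation: a parental group is consistent iff no SV has two
contradictory non-unknown alleles.  Conflicted contigs are moved
greedily (fewest hits first, keeping moves that lower the conflict
count); if conflicts remain and ≤ 10 contigs are involved, all 2^n
assignments are searched and the fewest-moves consistent one taken.
No consistent assignment means reported failure with the conflicting
SVs — a real outcome requiring manual curation, not an error.

Stitching: the backbone is copied; for each SV whose called allele
differs from the backbone's, the span from the end of the left anchor
gene to the start of the right anchor gene is replaced by the donor
allele's corresponding span (anchors always retained).  Unknown calls
keep the backbone.  Provenance tiles (interval → source) cover the
output without gaps or overlaps by construction.  The donor panel is a
pluggable config, so real reference segments can replace the
simulator-generated donors used in tests.

## Masking

Assembly contigs without a ≥ 1 kb primary alignment from any de novo
contig are dropped (the 1 kb support threshold is a documented default;
the sources leave it open).  Remaining zero-depth positions are
replaced by 'N', with depth computed as by
`samtools depth -a -g 0x100 -J`: all positions, secondary alignments
included, deletion-spanning reads covering their gap, duplicates and
QC-fails excluded.  Lengths are conserved; masked intervals are emitted
as BED; the operation is idempotent.  Assembler capitalization marks
are not required — the module stays assembler-agnostic.

## Simulator: what it emulates, and what it does not

Study conditions (fixed defaults): 10 V (2 pseudo) / 5 D / 3 J genes;
J spacing 200–350 bp (< 400 bp), D genes 16–36 bp (≤ 40), V spacing
1.8–2.6 kb; ~38 kb locus.  Read lengths uniform 8–14 kb — HiFi-like
scaled to the toy locus so reads span events with germline context on
both sides, as real HiFi reads do on the real locus.  Per-base
substitution rate 0.002 in noisy mode (HiFi-like), 0 in error-free
mode; no indel errors by default.  Depths of 4–30× are used in tests;
germline depth 10 and 20 junction-spanning reads per clone in the
acceptance run.

RSSs are fixed 7-mer markers planted flush against each gene so that
alignments split sharply at the annotated anchors; real
heptamer/nonamer/spacer structure, cryptic RSSs, repertoire frequency
bias, class-switch recombination and somatic hypermutation are *not*
modeled.  Truth alignments emulate aligner behaviour in two documented
ways: aligned pieces under 60 bp are left soft-clipped (the subsumed D
of a canonical event), and same-strand reference gaps under 2 kb are
emitted as CIGAR deletions rather than new segments (close D genes).
Consequently, passing tests demonstrate the correctness of the
decision rules and bookkeeping under ideal and lightly-noised
alignments — not robustness to real aligner idiosyncrasies, SVs beyond
the modeled catalog, or reference bias, which require real data.

## Numerical and degenerate-input choices

Ties in nearest-RSS lookup break toward the smaller gene start, then
the 5' side.  Reference-selection ties fall to panel priority.  Reads
absent from a reference rank last rather than erroring.  Empty junction
chains are contract violations in classification but simply mean "no
event" in profiling.  Simpson's index of an empty profile is undefined
and raises; profiles with no confident events report SI = None.  All
randomness flows through one seeded generator per run; identical
config + seed reproduce byte-identical outputs.
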