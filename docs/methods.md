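# Methods

## Scope and model

`hijackscan` implements the computational stages of an enhancer-hijacking
analysis: in-silico restriction digestion, 4C-seq read processing and signal
tracks, translocation breakpoint calling from paired/split capture reads,
derivative-chromosome coordinate maps, and CTCF-orientation / enhancer-module
analyses. Everything runs on synthetic data from the package's own generator,
so the pipeline is testable end-to-end at desk scale.

### Fragment maps

A genome is partitioned by a primary 4-cutter (default DpnII, `GATC`, cut
offset 0) into fragments; a secondary 4-cutter (default Csp6I, `GTAC`, cut
offset 1) defines per-fragment *end regions* — the sub-intervals from each
primary boundary to the nearest internal secondary cut, which are the parts a
4C library sequences. Fragments with no internal secondary cut are flagged
*blind* and retained by default (a `--exclude-blind`/`exclude_blind` switch
drops them from counting); retention is a package choice, since either
convention is defensible. Only palindromic recognition sequences are
supported: the forward-strand scan then finds every site, and non-palindromic
enzymes are rejected with a clear message. Coordinates are 0-based half-open
internally; BED export is unchanged, WIG is 1-based. Zero-length fragments
(cuts at contig edges or coincident cuts) are suppressed.

### 4C read processing

Reads are demultiplexed by exact (default) or bounded-mismatch prefix match
against viewpoint reading primers, which must end in the primary recognition
motif; clipping removes the primer bases before the motif, so trimmed reads
begin at the ligation junction. Assignment uses either (a) exact k-mer lookup
of the first k bases against a fragment-end catalog (both ends read inward,
right ends reverse-complemented), or (b) aligned single-end records filtered
by the boundary rule: a read is valid iff its strand-aware 5′ start lies
within `boundary_tolerance` (default 2 bp) of a fragment primary boundary.
Counting removes fragments within `exclusion_radius` fragments of the
viewpoint fragment (default 1; radius 0 still removes the viewpoint fragment
itself, i.e. self-ligation). Defaults for mismatch tolerance, boundary
tolerance and exclusion radius are explicit package choices recorded in
output headers. Every read lands in exactly one tally (kept / excluded /
unmapped / ambiguous / filtered); the conservation identity is asserted at
count time.

### Signal

RPM normalization divides by the total of *kept* counts (not raw sequenced
reads), so normalized profiles always total 1e6 and are comparable across
viewpoints; the denominator is recorded in the profile parameters. Smoothing
is a running mean over the fragment-ordered vector of one contig — window in
*fragments* (default 21, odd required), never spanning contigs — with shrink
edges (the mean is taken over existing positions only, so no signal is
invented beyond chromosome ends and constant vectors are fixed points). WIG
export anchors per-fragment values at 1-based fragment midpoints
(variableStep needs single positions); bedGraph preserves full intervals and
round-trips exactly. Fixed-bin coverage uses
`RPKM = count × 1e9 / (library_size × bin_size)` with a running mean over
`smooth_length / bin_size` bins (odd-ified by +1 when even, logged). The
contact-domain extent is the genomic span of the maximal run of consecutive
fragments at or above a fraction (default 0.5) of the regional maximum of the
smoothed signal.

### Breakpoint calling

The caller is a deliberately minimal pair-plus-split design. Discordant
pairs are mates on different contigs, or same-contig pairs with insert span
above `max_concordant_insert` (default 1000 bp) or non-FR orientation;
records below `min_mapq` (default 10) are dropped and counted. Candidates
come from single-linkage clustering within `cluster_window` (default
1000 bp) on *both* partners, per (ordered contig pair, orientation class);
clusters need `min_support` pairs (default 2) and report innermost read
edges. These defaults are package choices — the pair-based callers this
design follows do not fix them universally. Split-read refinement goes
beyond pair-based calling: for each junction-spanning read, every split
point with at least `min_match` (15) bases on both sides is tested for a
full prefix match in the partner-A flank window and suffix match in the
partner-B window; the modal (pos_a, pos_b) across reads wins, ties breaking
toward the smallest pos_a. Human-facing reports are 1-based (last retained
base of partner A / first retained base of partner B); internals are 0-based
half-open.

Junctions flanked by microhomology are only resolvable to a range, not a
base pair: if the bases on either side of the junction agree between the two
partners, adjacent split points explain the reads equally well. The caller
then still reports deterministically (smallest pos_a), but the synthetic
scenario builder (`make_translocation_scenario`) re-seeds its random filler
until the junction carries no single-base microhomology, so base-pair
recovery tests have a unique right answer.

### Derivative chromosomes

A `DerivativeChromosome` is an ordered list of oriented native segments.
`map_to`/`map_from` are mutually inverse on covered positions: for `+`
segments `der = offset + (pos − start)`; for `−` segments
`der = offset + (end − 1 − pos)`. Uncovered positions return `None` (a typed
absent result, not an exception). Segment orientation is always a user
input — it is not inferred from read evidence, because two-segment joins are
compatible with several reciprocal products.

### CTCF convergence and docking preservation

Loop-compatible pairs are (forward, reverse) site pairs with the forward
site first in coordinate order — on a single contig, or on derivative
coordinates after lifting site midpoints through `map_to` (sites not covered
by the derivative are dropped). `docking_preserved` encodes the
docking-site rule: the promoter-proximal forward CTCF site is preserved iff
the site interval and the promoter position are covered by the same
derivative segment and the site is not truncated by a segment boundary;
given preservation, a convergent partner is possible iff some
reverse-oriented site contributed by the joined partner segment lies
downstream of the docking site on the derivative. Upstream/downstream are
taken from coordinates and a user-supplied promoter strand, never from gene
names.

### Module quantification

Reads count toward an enhancer module iff they overlap it by ≥ 1 bp (once
per module at most); RPKM uses module length; with exactly two samples a
descriptive `log2((RPKM₁+1)/(RPKM₂+1))` fold change is added. No
significance test is attached: the quantification is descriptive by design,
and differential calls belong to dedicated count-model packages.

## Synthetic data: what it emulates, and what it does not

The generator plants primary/secondary recognition sites, oriented CTCF
motifs (a fixed 13-bp stand-in sequence free of restriction sites on both
strands) and module intervals into rejection-screened random filler, so
every site count is exact and no accidental motif occurrences exist.
Per-contig `origin` offsets let 200 kb toy sequences carry genome-scale
coordinates (e.g. a 3q26-style locus at 168.8 Mb).

4C reads are the viewpoint primer followed by the partner fragment's
left-end sequence continued past the shared motif; partners are drawn with
probability ∝ `background_rate · s^(−α) · enrichment`, cis on the supplied
(typically derivative) contig, `s` the fragment-midpoint separation. The
multiplicative form makes `background_rate` a pure scale that cancels under
normalization, and makes closed-form count ratios hold exactly (two
fragments at 10 kb vs 20 kb under α = 1 appear 2:1). Fragments within the
self-exclusion radius, fragments too short to fill a read, and
contig-terminal fragments whose left edge is not a genuine cut (no
motif-anchored junction read can arise there) are never sampled. Capture
pairs place a configurable fraction of inserts strictly across the junction
(mates clear of the junction base, hence cleanly discordant) and emit one
junction-crossing read per straddling insert as split evidence.

Defaults: α = 1.0 (a typical contact-decay slope in the sub-Mb regime),
enrichment 10 at anchor pairs, read length 75 bp, insert 400 ± 40 bp,
junction-span fraction 0.2. The contact model is a package construct — no
quantitative contact model is fitted to patient data — so passing tests show
the *pipeline* is correct (exact bookkeeping, recoverable parameters), not
that the model describes any particular dataset. The generator omits
sequencing errors, PCR duplicates, mappability structure and quality-score
realism (constant qualities); consequently, 100% read recovery is the
correct expectation here, whereas real libraries lose reads at every stage.

## Problem sizes and numerical choices

Tests and the acceptance script use a 200-fragment (80 kb) 4C locus with a
central viewpoint and a 21-fragment anchor zone; 10,000 reads for exact
recovery checks, 50,000 for decay-slope (tolerance ±0.15) and
loop-enrichment (≥ 3× distance-matched background after window-21
smoothing) checks; 100 random 10-kb sequences for digestion-oracle
equivalence; breakpoint scenarios use two 200-kb contigs and 300 capture
pairs. All randomness flows through explicit integer seeds; identical
configuration yields byte-identical outputs. Running means use a cumulative
sum (exact for these magnitudes); RPM conservation is asserted to 1e-6.

## Known limitations

- Only palindromic restriction enzymes; no multi-enzyme cocktails.
- The k-mer end-catalog mapper is exact-match only — a desk-scale stand-in
  for a gapped aligner, not a replacement.
- The SV caller handles two-segment joins and simple inversions; no CNVs,
  insertions, or multi-breakpoint chains.
- Junction microhomology limits split-read resolution to a range; the
  caller reports a deterministic representative rather than the interval.
- Module fold changes are descriptive; no dispersion model or testing.
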