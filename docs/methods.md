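# Methods

## Graph model and parsing

A GFA1 file is reduced to unitigs (S records) and exact-overlap links
(L records); all other record types are skipped. Only `<int>M`, `0M` and `*`
overlap CIGARs are accepted — the sequence-reconstruction step trims overlaps
as exact duplicates, which is meaningless for gapped overlaps, so anything
containing I/D/X operations is a hard error rather than a silent
approximation. Segments with `*` sequences are kept (length from `LN:i`) and
are usable for enumeration and counting, but not for sequence export.

The graph is bidirected: every L record implies its reverse-complement dual
(`to′ → from′`), and both directions are materialized at load so traversal
never special-cases strand. Read depth is taken from the first present of
`rd:i`, `dp:f`, `DP:f`, or derived as `RC:i / length`; this precedence is a
package convention — assemblers disagree and no single tag is universal.
Dialect detection (hifiasm / Verkko / Shasta / minigraph / generic) is based
on segment ID patterns and tags and affects nothing but metadata; minigraph
`SN/SO/SR` rGFA tags are not given stable-coordinate semantics.

## Path enumeration

A candidate contig between flanking unitigs is an oriented walk in which no
unitig ID occurs twice, *in either orientation*. Forbidding opposite-
orientation recurrence is a deliberate choice: it encodes "no assembly path
loops through a unitig multiple times" and excludes palindromic loops, at the
cost of missing the exotic case of a genuine inverted repeat traversed twice.
ID-simplicity also automatically keeps alternate unitigs of one bubble out of
a single path, so no separate bubble detector is needed.

Enumeration is depth-first with children visited in lexicographic
(ID, orientation) order, with `+` before `-`; output order is therefore a
pure function of the input bytes, and FASTA numbering is reproducible. The
start unitig is tried in `+` orientation and falls back to `-` only when no
`+` path exists (`--start-orient` pins it). A hard cap (default 100 000
paths) guards the exponential worst case; exceeding it is an error in
enumeration and a `>cap` sentinel in genome-wide counting. Enumeration
recurses one frame per path step, so it is comfortable for regions up to a
few hundred unitigs deep — the intended scale — rather than chromosome-length
chains.

Phased mode restricts interior unitigs to one haplotype's ID set plus all
unitigs in *neither* set (shared sequence present in both haplotype
assemblies); the flanking unitigs are exempt. A region is classified
**unresolved** when any unrestricted path mixes interior unitigs of both
haplotype sets. Note a consequence: two successive heterozygous bubbles
joined by a shared anchor are unresolved under this rule, because a path can
legally switch haplotype at the anchor — the graph genuinely does not
determine the phase relationship between separate bubbles. A resolvable
region is therefore one large haplotype bubble (possibly with small bubbles
nested inside each branch). Unresolved regions are reported as a single
record over all paths rather than per haplotype.

Sequence reconstruction concatenates oriented unitig sequences, trimming
each link's overlap from the downstream sequence; the result length is
always Σ unitig lengths − Σ overlaps, which the tests verify path by path.

`genome_wide_path_counts` extends the same enumeration to a whole graph: per
weakly connected component (networkx), *tips* — unitigs lacking an oriented
successor on at least one side — are paired (all unordered pairs) and the
ID-simple paths between each pair counted. Single-unitig components count 1;
a cyclic component with no tips yields one zero-count row. This tip-pairing
convention is the package's own; it reports tip pairs with no connecting
oriented path as count 0 rather than suppressing them.

## Copy-number uncertainty

A path's copy number is the orientation-independent sum of per-unitig feature
counts; unitigs missing from the count table contribute 0 with a warning
(absence of annotation is not evidence of absence, but halting would be
worse). Per record: margin = max − min; percent uncertainty =
100·margin/max, rounded to two decimals, and defined as 0 when max = 0; the
median is taken over the multiset of per-path values, so duplicate copy
numbers are weighted by path multiplicity (even path counts can give
half-integer medians). Dividing by the maximum makes the percentage read as
"this fraction of the largest possible copy number is not supported by every
possible assembly."

`count_motif_copies` is a deliberately small stand-in for real gene
annotation (protein-to-genome alignment plus intactness criteria): it counts
non-overlapping motif occurrences on either strand, greedily left to right,
with an optional identity threshold. It exists so synthetic fixtures can
carry "genes" with analytically known counts; it is not a gene finder.

No regression of percent uncertainty on copy number is provided; the
reporting stops at the per-record summary.

## Switch-error screen

Per-read clip geometry comes from the CIGAR: left/right soft-clip lengths
(leading/trailing hard clips are skipped when locating them) and aligned
bases as the summed lengths of M/=/X/I/D operations. Windows of `window` bp
(default 10 kb) tile each contig every `step` bp (default window/2 — a
"sliding" window with half overlap; the step is configurable because no
canonical value exists). Each primary mapped read contributes to exactly one
window — the one whose start is the largest window start at or before the
read's alignment start — a deterministic rule that keeps window statistics
independent of coverage-weighted double counting. Secondary and unmapped
records are always excluded; supplementary records are excluded by default
(the clip signal of interest lives on the primary record) with a flag to
include them. `--min-clip` (default 1 bp) zeroes side clips shorter than the
threshold, for adapter-trimming artifacts.

Window statistics: C = total soft-clipped bases over total aligned bases
(0 when empty); S = *population* variance of dᵢ = leftᵢ − rightᵢ over **all**
reads in the window, unclipped reads contributing dᵢ = 0 (fewer than two
reads ⇒ 0); P counts reads clipped strictly more on one side — reads clipped
equally on both sides enter the denominator but neither side — and is 0 when
nothing is clipped. Index = C(1+P)²S. Including unclipped reads in S damps
variance in well-covered windows; the alternative (clipped reads only,
sample variance) changes absolute index values but not the peak-at-junction
behaviour the screen is validated on, which is why no absolute index
threshold is offered: the tool ranks windows for inspection, it does not
call verdicts. Window statistics are not decomposable: the variance of a
window is not the mean of its halves' variances, and a test documents this
to guard against naive parallelization.

## Synthetic fixtures

`make_bubble_graph` builds one large haplotype bubble: a shared start anchor
diverges into two haplotype branches that reconverge at a shared end anchor;
each branch is a chain of sites, and a site with k ≥ 2 alternatives is a
nested small bubble (entry → alternatives → exit). Defaults: unitig lengths
uniform in 400–800 bp, overlaps 20–60 bp, planted copies per alternative
uniform in 0–4 — small enough to enumerate instantly, large enough that
overlap trimming and motif planting interact nontrivially. Every link is
exact-overlap-consistent (downstream prefix equals upstream suffix), and
after construction every unitig's realized motif count is re-verified
against its planted count (filler bases are redrawn on the rare accidental
occurrence), so the truth table is exact, not probabilistic. Optional cross
links join the two branches with probability `cross_link_rate` per site,
reproducing the misassembly topology that makes a region unresolvable. All
generation is seed-deterministic and byte-identical across runs.

`make_divergent_haplotypes` produces two equal-length sequences identical
outside planted divergent intervals: a few short interior intervals (shorter
than a read, so their clip signals are two-sided within one window) and one
extended non-homologous tail. Fusing haplotype 1's head to haplotype 2's
tail at the start of that region (`fuse_at_junction` /
`make_switch_error_fasta`) yields a reference with an artificial switch
error at a junction beyond which the displaced haplotype has no homology.

`simulate_clipped_reads` draws error-free reads (default 5 kb, 20× total
depth split across haplotypes) and aligns them by exact anchoring at their
true coordinate: full match where read equals reference, otherwise the
longer exactly-matching end (≥ 50 bp) anchors and the rest is soft-clipped;
unanchorable reads are dropped as unmapped. Multi-contig references model a
phased assembly, each haplotype's reads going to its own contig — the
"hapmer" alignment the screen expects. With the intact phased control every
read matches perfectly (index identically 0), while the fused contig
produces right-clips from haplotype-1 reads at the junction and nothing
mappable inside the non-homologous tail, giving a single polarized peak.

What this does *not* emulate: sequencing error, chimeric reads, mapping-
quality ambiguity in repeats, indel-containing alignments, coverage bias,
or a real aligner's clipping heuristics. Passing tests therefore demonstrate
the statistics and the enumeration are correct on clean signal; on real data
the index is noisier and peak heights are aligner- and preset-dependent
(ONT presets, for instance, clip more permissively than HiFi presets).

## Problem sizes and numerics

Tests and the acceptance script run on graphs of ≤ ~25 unitigs, 30–50
generator seeds, and 120 kb switch-error genomes at 20× — sizes chosen so
exhaustive enumeration and its brute-force oracle stay exact and instant
while still exercising branching, nesting, strand reversal and overlap
trimming. Floating-point comparisons in reports are exact except percent
uncertainty, which is defined *as* a 2-decimal rounded quantity. Degenerate
inputs return zeros (empty windows, unclipped reads) or explicit errors
(zero paths, missing sequences, malformed records) rather than NaNs.
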