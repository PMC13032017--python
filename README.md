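# gfawalk

Tools for asking two questions about a phased long-read genome assembly:

1. **How certain is the assembly of a region?** The raw unitig graph (the
   GFA an assembler like hifiasm, Verkko or Shasta emits *before* bubble
   popping and purging) still contains every alternative unitig. `gfawalk`
   enumerates **all** directed, acyclic paths between two flanking unitigs —
   every contig the assembler could have produced — per haplotype or
   unphased, and reconstructs each path's FASTA sequence with overlap- and
   strand-aware concatenation. Given per-unitig feature counts (e.g. intact
   gene copies in a tandem array), it turns the spread of per-path copy
   numbers into a margin of error and a percent uncertainty, so a claimed
   copy-number variant can be checked against assembly ambiguity instead of
   trusted blindly.
2. **Did phasing switch haplotypes mid-contig?** When the assembly's own
   long reads are realigned to a phased contig, a switch error leaves a
   polarized soft-clipping scar at the junction. `gfawalk` scans sliding
   windows of a SAM/BAM and computes a switch-error risk index from CIGAR
   soft clips.

This matters most in repetitive tandem gene arrays — the motivating case is
type III antifreeze protein (AFP) arrays in polar fishes, where haplotypes
differ in gene copy number and assemblers must choose one of many paths
through the array.

## The model

**Path enumeration.** A GFA is a bidirected string graph: unitigs are nodes,
L records are oriented exact overlaps, and every link also implies its
reverse-complement traversal. A candidate contig from unitig *s* to unitig
*t* is an oriented walk in which no unitig ID recurs (in either
orientation), so alternate branches of one bubble can never co-occur in a
path. In phased mode, each haplotype may use its own unitigs plus any unitig
assigned to neither haplotype (shared, homozygous sequence). A region is
**unresolved** when some unrestricted walk mixes interior unitigs of both
haplotypes — the graph interconnects the bubble's sides and the haplotypes
cannot be distinguished; it is then summarized as a single record over all
paths.

**Copy-number uncertainty.** With per-unitig counts *c(u)*, a path's copy
number is Σ *c(u)* over its unitigs. Per haplotype (or per unresolved
region) over all *n* paths:

    margin = max − min
    percent uncertainty = 100 · margin / max      (0 when max = 0)
    median = median of the n per-path copy numbers

**Switch-error index.** Per window, from primary alignments:

    C = soft-clipped bases / (matched + inserted + deleted bases)
    S = var(left_clip_i − right_clip_i)            over all reads i
    P = |n_left − n_right| / n_clipped             ∈ [0, 1]

    Index = C · (1 + P)² · S

The squared polarization term grows the index as clipping becomes one-sided
across reads, but is 1 (not 0) at P = 0 so skewed clipping is never erased.
The screen needs the long reads the assembly was built from; short reads are
rarely clipped and give false negatives.

## Worked example

Everything is generatable — no downloads. Build a planted haplotype-bubble
fixture (haplotype 1 carries a nested small bubble with different planted
gene counts on its two alternatives), then enumerate and summarize:

```bash
gfawalk fixtures --n-bubbles 2 --branches 2,1 --seed 7 --out fx
gfawalk parse-phased --gfa fx/graph.gfa --hap1 fx/hap1.txt --hap2 fx/hap2.txt \
    --start anchor_start --end anchor_end --counts fx/counts.tsv --out region
```

```
region is resolved
wrote 4 path FASTA(s) to region
```

`region/summary.tsv` — two possible contigs per haplotype, with exact
reconstructed lengths:

```
path_id   haplotype  n_unitigs  length
path0001  hap1       6          3265
path0002  hap1       6          3441
path0001  hap2       6          3162
path0002  hap2       6          3141
```

`region/uncertainty.tsv` — haplotype 1's two paths carry 4 and 5 planted
gene copies, so its copy number is uncertain by 1 copy (20% of the maximum
5); haplotype 2's alternatives happen to carry equal counts, so its copy
number is assembly-robust:

```
record  resolution  n_paths  min  max  margin  percent_uncertainty  median
hap1    resolved    2        4    5    1       20.0                 4.5
hap2    resolved    2        4    4    0       0.0                  4.0
```

The switch-error screen runs the same way from the shell
(`gfawalk simulate` to build a fused switch-error reference plus reads,
`gfawalk screen` to scan it); the window containing the fused junction
carries the genome-wide maximum index with polarization P = 1, while the
intact control scans flat at 0.

The same operations are available as a library:

```python
from gfawalk import parse_gfa, HaplotypeSpec, phased_paths, region_uncertainty
```

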