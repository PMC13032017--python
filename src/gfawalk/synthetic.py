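"""Synthetic assembly-graph and alignment fixtures with known ground truth.

Everything the toolkit consumes can be generated here, seed-deterministically:

* bubble graphs — a shared-anchor backbone with one haplotype bubble per
  heterozygous region, optionally nested small bubbles (several alternative
  unitigs per haplotype branch), planted motif "gene" copies per branch, and
  optional artifact cross links joining the two haplotype sides (the
  misassembly topology that makes a region unresolvable);
* switch-error references — two haplotype sequences of equal length that
  diverge in marked intervals, fused so the 5' end of haplotype 1 meets the
  3' end of haplotype 2 at the start of an extended non-homologous region;
* clipped-read alignments — error-free reads drawn from the haplotype
  sequences and aligned to a reference by exact anchoring, so a read spanning
  a divergence point is soft-clipped on the non-matching side with an exact,
  analytically known geometry.

Reads are error-free by design: the switch screen's signal is clip geometry,
not base error, and exact anchoring keeps the expected alignments analytic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .cnv import count_motif_copies
from .graph_io import AssemblyGraph, Link, Unitig, write_fasta, write_gfa

__all__ = [
    "GraphRecipe",
    "BubbleGraphFixture",
    "make_bubble_graph",
    "make_divergent_haplotypes",
    "fuse_at_junction",
    "make_switch_error_fasta",
    "simulate_clipped_reads",
]

_BASES = "ACGT"
DEFAULT_MOTIF = "ATGGCCTGCAAC"  # arbitrary 12-mer standing in for a gene


@dataclass(frozen=True)
class GraphRecipe:
    """Parameters of a planted haplotype-bubble graph.

    The graph is one large haplotype bubble: a shared start anchor diverges
    into two haplotype branches that reconverge at a shared end anchor. Each
    branch is a chain of ``n_bubbles`` sites; site ``i`` holds
    ``branch_counts[i]`` alternative unitigs (1 = a plain segment, >=2 = a
    nested small bubble with that many alternatives). A ``branch_counts``
    entry may also be a ``(hap1, hap2)`` pair to give the two haplotype
    branches different small-bubble structure.

    ``copies_per_branch[hap][i][j]`` plants that many motif copies on
    alternative ``j`` of site ``i`` of haplotype ``hap`` in {"hap1", "hap2"};
    when None, counts are drawn uniformly from 0..4. ``cross_link_rate`` is
    the per-site probability of an artifact link joining the two haplotype
    branches (the misassembly topology; any such link makes the region
    unresolvable).
    """

    n_bubbles: int = 2
    branch_counts: tuple[int | tuple[int, int], ...] = (1, 1)
    unitig_length_range: tuple[int, int] = (400, 800)
    overlap_range: tuple[int, int] = (20, 60)
    motif: str = DEFAULT_MOTIF
    copies_per_branch: Mapping[str, Sequence[Sequence[int]]] | None = None
    cross_link_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bubbles < 1:
            raise ValueError("need at least one site per branch")
        if len(self.branch_counts) != self.n_bubbles:
            raise ValueError("branch_counts must have one entry per site")
        if any(min(self.site_counts(i)) < 1 for i in range(self.n_bubbles)):
            raise ValueError("branch counts must be >= 1")
        lo, hi = self.unitig_length_range
        omin, omax = self.overlap_range
        if not (1 <= omin <= omax):
            raise ValueError("overlap range must satisfy 1 <= min <= max")
        if omax >= lo:
            raise ValueError("max overlap must be below min unitig length")
        if 2 * omax + len(self.motif) + 2 > lo:
            raise ValueError(
                "unitigs too short to hold overlap regions plus motif copies"
            )
        if not 0.0 <= self.cross_link_rate <= 1.0:
            raise ValueError("cross_link_rate must be in [0, 1]")

    def site_counts(self, i: int) -> tuple[int, int]:
        """(hap1, hap2) alternative counts at site ``i``."""
        entry = self.branch_counts[i]
        if isinstance(entry, int):
            return entry, entry
        k1, k2 = entry
        return int(k1), int(k2)


@dataclass
class BubbleGraphFixture:
    """A generated bubble graph plus its ground truth and on-disk files."""

    graph: AssemblyGraph
    start_id: str
    end_id: str
    hap_ids: dict[str, list[str]]
    unitig_counts: dict[str, int]
    truth: pd.DataFrame  # haplotype, path, copy_number
    resolved: bool
    gfa_path: Path
    hap1_list_path: Path
    hap2_list_path: Path
    counts_path: Path
    truth_path: Path

    def truth_extremes(self, hap: str) -> tuple[int, int]:
        vals = self.truth.loc[self.truth["haplotype"] == hap, "copy_number"]
        return int(vals.min()), int(vals.max())


def _random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


class _SeqBuilder:
    """A unitig sequence under construction: pinned overlap ends, planted
    motif spans, free filler bases that may be redrawn until the realized
    motif count equals the planted count."""

    def __init__(self, rng: random.Random, length: int, motif: str) -> None:
        self.rng = rng
        self.length = length
        self.motif = motif
        self.chars = list(_random_dna(rng, length))
        self.pin_prefix = 0
        self.pin_suffix = 0
        self.planted: list[tuple[int, str]] = []  # (position, oriented motif)

    def pin(self, prefix: str | None = None, suffix: str | None = None) -> None:
        if prefix is not None:
            self.chars[: len(prefix)] = prefix
            self.pin_prefix = max(self.pin_prefix, len(prefix))
        if suffix is not None:
            self.chars[self.length - len(suffix):] = suffix
            self.pin_suffix = max(self.pin_suffix, len(suffix))

    def plant(self, copies: int, revcomp_of: str) -> None:
        """Place ``copies`` non-overlapping motif copies (random strand) in the
        unpinned middle, separated by at least one spacer base."""
        k = len(self.motif)
        span = self.length - self.pin_prefix - self.pin_suffix
        slack = span - copies * (k + 1)
        if slack < 0:
            raise ValueError("unitig too short for planted motif copies")
        gaps = [0] * (copies + 1)
        for _ in range(slack):
            gaps[self.rng.randrange(copies + 1)] += 1
        pos = self.pin_prefix
        for j in range(copies):
            pos += gaps[j] + (1 if j > 0 else 0)
            oriented = self.motif if self.rng.random() < 0.5 else revcomp_of
            self.chars[pos : pos + k] = oriented
            self.planted.append((pos, oriented))
            pos += k
        if copies:
            self.planted.sort()

    def finalize(self, target_copies: int, max_tries: int = 200) -> str:
        """Redraw free filler bases until the motif count equals the target."""
        planted_spans = [(p, p + len(self.motif)) for p, _ in self.planted]
        free = [
            i
            for i in range(self.pin_prefix, self.length - self.pin_suffix)
            if not any(a <= i < b for a, b in planted_spans)
        ]
        for _ in range(max_tries):
            seq = "".join(self.chars)
            if count_motif_copies(seq, self.motif) == target_copies:
                return seq
            for i in free:
                self.chars[i] = self.rng.choice(_BASES)
        raise RuntimeError(
            "could not realize the planted motif count; unitig too constrained"
        )


def _resolve_copies(
    recipe: GraphRecipe, rng: random.Random
) -> dict[str, list[list[int]]]:
    ks = {
        "hap1": [recipe.site_counts(i)[0] for i in range(recipe.n_bubbles)],
        "hap2": [recipe.site_counts(i)[1] for i in range(recipe.n_bubbles)],
    }
    if recipe.copies_per_branch is not None:
        out = {
            h: [list(b) for b in recipe.copies_per_branch[h]]
            for h in ("hap1", "hap2")
        }
        for h in ("hap1", "hap2"):
            if len(out[h]) != recipe.n_bubbles or any(
                len(out[h][i]) != ks[h][i] for i in range(recipe.n_bubbles)
            ):
                raise ValueError(
                    "copies_per_branch shape must match n_bubbles/branch_counts"
                )
        return out
    return {
        h: [[rng.randrange(0, 5) for _ in range(ks[h][i])]
            for i in range(recipe.n_bubbles)]
        for h in ("hap1", "hap2")
    }


def make_bubble_graph(recipe: GraphRecipe, outdir: str | Path) -> BubbleGraphFixture:
    """Generate a planted bubble graph and write GFA, haplotype lists, a
    per-unitig counts TSV and a truth table to ``outdir``.

    Topology: a shared start anchor diverges into two haplotype branches that
    reconverge at a shared end anchor (one large haplotype bubble). Each
    branch is a chain of sites; a site with k >= 2 alternatives is a nested
    small bubble (entry -> alternatives -> exit). Every link is exact-overlap
    and consistent — downstream prefixes equal upstream suffixes — so path
    sequences reconstruct exactly, and the realized motif count of every
    unitig is verified against the planted count, making the truth table
    exact by construction. Optional cross links join the two haplotype
    branches, which makes the region unresolvable.
    """
    from .graph_io import reverse_complement

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(recipe.seed)
    motif_rc = reverse_complement(recipe.motif)
    lo, hi = recipe.unitig_length_range
    omin, omax = recipe.overlap_range
    copies = _resolve_copies(recipe, rng)

    def new_builder() -> _SeqBuilder:
        return _SeqBuilder(rng, rng.randint(lo, hi), recipe.motif)

    sequences: dict[str, str] = {}
    planted: dict[str, int] = {}
    links: list[Link] = []
    hap_ids: dict[str, list[str]] = {"hap1": [], "hap2": []}

    def finalize(uid: str, builder: _SeqBuilder, n_copies: int) -> str:
        seq = builder.finalize(n_copies)
        sequences[uid] = seq
        planted[uid] = n_copies
        return seq

    def rand_overlap() -> int:
        return rng.randint(omin, omax)

    # the two shared anchors flanking the haplotype bubble, motif-free
    start_id, end_id = "anchor_start", "anchor_end"
    for a in (start_id, end_id):
        finalize(a, new_builder(), 0)

    # each haplotype branch is a left-to-right chain of sites; each node's
    # prefix is pinned from its upstream donor, and the branch's final node
    # gets its suffix pinned from the end anchor's prefix
    cross_ends: dict[str, list[str]] = {"hap1": [], "hap2": []}
    for hap_idx, hap in enumerate(("hap1", "hap2")):
        prev = start_id  # upstream donor node of the next site
        for i in range(recipe.n_bubbles):
            k = recipe.site_counts(i)[hap_idx]
            last_site = i == recipe.n_bubbles - 1
            donor_seq = sequences[prev]
            if k == 1:
                uid = f"{hap}_s{i}_alt0"
                b = new_builder()
                ov_in = rand_overlap()
                b.pin(prefix=donor_seq[-ov_in:])
                if last_site:
                    ov_out = rand_overlap()
                    b.pin(suffix=sequences[end_id][:ov_out])
                b.plant(copies[hap][i][0], motif_rc)
                finalize(uid, b, copies[hap][i][0])
                links.append(Link(prev, "+", uid, "+", ov_in))
                if last_site:
                    links.append(Link(uid, "+", end_id, "+", ov_out))
                hap_ids[hap].append(uid)
                prev = uid
            else:
                entry, exit_ = f"{hap}_s{i}_in", f"{hap}_s{i}_out"
                eb, ob = new_builder(), new_builder()
                ov_in = rand_overlap()
                eb.pin(prefix=donor_seq[-ov_in:])
                if last_site:
                    ov_out = rand_overlap()
                    ob.pin(suffix=sequences[end_id][:ov_out])
                eseq = finalize(entry, eb, 0)
                oseq = finalize(exit_, ob, 0)
                links.append(Link(prev, "+", entry, "+", ov_in))
                if last_site:
                    links.append(Link(exit_, "+", end_id, "+", ov_out))
                hap_ids[hap] += [entry, exit_]
                ov_e, ov_o = rand_overlap(), rand_overlap()
                for j in range(k):
                    uid = f"{hap}_s{i}_alt{j}"
                    b = new_builder()
                    b.pin(prefix=eseq[-ov_e:], suffix=oseq[:ov_o])
                    b.plant(copies[hap][i][j], motif_rc)
                    finalize(uid, b, copies[hap][i][j])
                    links.append(Link(entry, "+", uid, "+", ov_e))
                    links.append(Link(uid, "+", exit_, "+", ov_o))
                    hap_ids[hap].append(uid)
                prev = exit_
            cross_ends[hap].append(prev)

    cross_links: list[Link] = []
    for i in range(recipe.n_bubbles):
        if rng.random() < recipe.cross_link_rate:
            # misassembly artifact: the hap1 branch feeds into the hap2 branch
            # at site i with a zero-length overlap
            cross = Link(cross_ends["hap1"][i], "+", cross_ends["hap2"][i], "+", 0)
            cross_links.append(cross)
            links.append(cross)

    unitigs = {
        uid: Unitig(uid, seq, len(seq), depth=float(rng.randint(1, 40)))
        for uid, seq in sequences.items()
    }
    graph = AssemblyGraph(unitigs, links, dialect="generic")

    # ground-truth paths: one per combination of site alternatives per haplotype
    rows = []
    for hap in ("hap1", "hap2"):
        per_site = [copies[hap][i] for i in range(recipe.n_bubbles)]
        for combo in product(*(range(len(c)) for c in per_site)):
            total = sum(per_site[i][j] for i, j in enumerate(combo))
            name = ";".join(f"s{i}:alt{j}" for i, j in enumerate(combo))
            rows.append({"haplotype": hap, "path": name, "copy_number": total})
    truth = pd.DataFrame(rows, columns=["haplotype", "path", "copy_number"])

    gfa_path = outdir / "graph.gfa"
    write_gfa(graph, gfa_path)
    hap_paths = {}
    for hap in ("hap1", "hap2"):
        p = outdir / f"{hap}.txt"
        p.write_text(
            f"# {hap} unitigs\n" + "".join(u + "\n" for u in hap_ids[hap])
        )
        hap_paths[hap] = p
    counts_path = outdir / "counts.tsv"
    counts_path.write_text(
        "unitig_id\tcopies\n"
        + "".join(f"{u}\t{planted[u]}\n" for u in sorted(planted))
    )
    truth_path = outdir / "truth.tsv"
    truth.assign(resolved=not cross_links).to_csv(
        truth_path, sep="\t", index=False
    )

    return BubbleGraphFixture(
        graph=graph,
        start_id=start_id,
        end_id=end_id,
        hap_ids=hap_ids,
        unitig_counts=planted,
        truth=truth,
        resolved=not cross_links,
        gfa_path=gfa_path,
        hap1_list_path=hap_paths["hap1"],
        hap2_list_path=hap_paths["hap2"],
        counts_path=counts_path,
        truth_path=truth_path,
    )


def make_divergent_haplotypes(
    length: int = 120_000,
    n_short_div: int = 3,
    short_div_len: int = 1_500,
    tail_div_len: int = 25_000,
    seed: int = 0,
) -> tuple[str, str, int]:
    """Two equal-length haplotype sequences with planted divergence.

    ``n_short_div`` short intervals in the first part of the sequence and one
    extended non-homologous tail differ between the haplotypes; everywhere
    else the sequences are identical (exact homology). Returns
    ``(hap1, hap2, junction)`` where ``junction`` is the start of the tail —
    the natural fusion point for a simulated switch error.
    """
    if tail_div_len + (n_short_div + 1) * 2 * short_div_len > length:
        raise ValueError("divergent intervals do not fit in the sequence")
    rng = random.Random(seed)
    hap1 = list(_random_dna(rng, length))
    hap2 = hap1.copy()
    junction = length - tail_div_len
    # short divergent intervals, evenly spread over the homologous head
    head = junction - short_div_len
    for i in range(n_short_div):
        start = (i + 1) * head // (n_short_div + 1)
        hap2[start : start + short_div_len] = _random_dna(rng, short_div_len)
    hap2[junction:] = _random_dna(rng, tail_div_len)
    return "".join(hap1), "".join(hap2), junction


def fuse_at_junction(seq1: str, seq2: str, junction: int) -> str:
    """Fuse the 5' end of ``seq1`` with the 3' end of ``seq2`` at ``junction``."""
    if not 0 <= junction <= min(len(seq1), len(seq2)):
        raise ValueError("junction must lie within both sequences")
    return seq1[:junction] + seq2[junction:]


def make_switch_error_fasta(
    hap1: str | Path, hap2: str | Path, junction: int, out: str | Path
) -> Path:
    """Build a simulated switch-error reference from two haplotype FASTAs.

    The output contig is ``hap1[:junction] + hap2[junction:]``; the header
    records the junction coordinate.
    """
    rec1 = next(SeqIO.parse(str(hap1), "fasta"))
    rec2 = next(SeqIO.parse(str(hap2), "fasta"))
    fused = fuse_at_junction(str(rec1.seq), str(rec2.seq), junction)
    out = Path(out)
    write_fasta([(f"switch_error|junction={junction}", fused)], out)
    return out


def _common_prefix_suffix(a: str, b: str) -> tuple[int, int]:
    """Lengths of the common prefix and common suffix of two equal-length strings."""
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    neq = np.flatnonzero(arr_a != arr_b)
    if neq.size == 0:
        return len(a), len(a)
    return int(neq[0]), len(a) - 1 - int(neq[-1])


def simulate_clipped_reads(
    reference: str | Path,
    truth_haplotypes: Sequence[str | Path],
    read_length: int = 5_000,
    depth: float = 20.0,
    seed: int = 0,
    out: str | Path = "reads.sam",
    contig_for_hap: Sequence[str] | None = None,
    min_anchor: int = 50,
) -> Path:
    """Simulate error-free haplotype reads aligned to a reference by exact
    anchoring, emitting coordinate-sorted SAM.

    Reads are drawn uniformly from each truth haplotype; each haplotype is
    assigned a reference contig (``contig_for_hap``, defaulting to contigs in
    order, or the single contig for all haplotypes). A read identical to the
    reference window at its coordinate maps fully; a read diverging from it is
    anchored on its longer exactly-matching end and soft-clipped on the other;
    a read with no anchor of at least ``min_anchor`` bases is dropped as
    unmapped. Total depth is split evenly across haplotypes.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = random.Random(seed)
    ref_records = {
        r.id: str(r.seq).upper() for r in SeqIO.parse(str(reference), "fasta")
    }
    ref_names = list(ref_records)
    haps = [
        str(next(SeqIO.parse(str(p), "fasta")).seq).upper()
        for p in truth_haplotypes
    ]
    if contig_for_hap is None:
        if len(ref_names) == len(haps):
            contig_for_hap = ref_names
        elif len(ref_names) == 1:
            contig_for_hap = ref_names * len(haps)
        else:
            raise ValueError(
                "cannot infer haplotype-to-contig assignment; pass contig_for_hap"
            )

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": len(ref_records[n])} for n in ref_names],
    }
    records: list[tuple[int, int, str, str, str]] = []
    for h, (hap_seq, contig) in enumerate(zip(haps, contig_for_hap)):
        target = ref_records[contig]
        if len(target) != len(hap_seq):
            raise ValueError(
                f"haplotype {h + 1} and contig {contig!r} lengths differ; "
                "exact anchoring needs coordinate-compatible sequences"
            )
        if read_length > len(hap_seq):
            raise ValueError("read_length exceeds haplotype length")
        n_reads = round(depth * len(hap_seq) / (len(haps) * read_length))
        tid = ref_names.index(contig)
        for i in range(n_reads):
            p = rng.randrange(0, len(hap_seq) - read_length + 1)
            read = hap_seq[p : p + read_length]
            window = target[p : p + read_length]
            pref, suf = _common_prefix_suffix(read, window)
            if pref == read_length:
                records.append((tid, p, f"{read_length}M", read,
                                f"hap{h + 1}_read{i:05d}"))
            elif pref >= suf and pref >= min_anchor:
                records.append(
                    (tid, p, f"{pref}M{read_length - pref}S", read,
                     f"hap{h + 1}_read{i:05d}")
                )
            elif suf > pref and suf >= min_anchor:
                records.append(
                    (tid, p + read_length - suf,
                     f"{read_length - suf}S{suf}M", read,
                     f"hap{h + 1}_read{i:05d}")
                )
            # else: no usable anchor -> unmapped, not emitted

    records.sort(key=lambda r: (r[0], r[1], r[4]))
    out = Path(out)
    with pysam.AlignmentFile(str(out), "wh", header=header) as af:
        for tid, pos, cigar, seq, qname in records:
            seg = pysam.AlignedSegment(af.header)
            seg.query_name = qname
            seg.flag = 0
            seg.reference_id = tid
            seg.reference_start = pos
            seg.mapping_quality = 60
            seg.cigarstring = cigar
            seg.query_sequence = seq
            af.write(seg)
    return out
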