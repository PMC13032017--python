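"""Sliding-window switch-error risk index from soft-clipped long reads.

A switch error — a change from one parental haplotype to the other within a
single contig of a phased assembly — leaves a characteristic alignment scar
when the reads used to assemble the haplotype are realigned to it: reads
spanning the junction match on one side and are soft-clipped on the other,
with the clipping polarized to the same side across reads. Over sliding
windows, three statistics are computed from CIGAR soft clips:

* ``C`` — soft-clipped bases divided by the sum of matched, inserted and
  deleted bases in the window (clip burden);
* ``S`` — variance of the per-read difference between left and right
  soft-clipped bases (one-sidedness of clipping within reads);
* ``P`` — |#reads clipped more on the left − #reads clipped more on the
  right| / #clipped reads (polarization across reads, in [0, 1]).

The risk index is ``C * (1 + P)**2 * S``: the squared polarization term makes
the index grow faster as clipping becomes one-sided, but evaluates to 1 (not
0) when P = 0 so skewed clipping without polarization is still flagged.

The screen requires the long reads that were used to assemble the reference;
short reads are rarely soft-clipped and would yield false negatives.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "ReadClipStats",
    "cigar_clip_stats",
    "window_statistics",
    "switch_index",
    "switch_error_scan",
    "write_bedgraph",
]

WINDOW_COLUMNS = [
    "contig",
    "win_start",
    "win_end",
    "n_reads",
    "n_clipped",
    "C",
    "S",
    "P",
    "index",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_ALIGNED_OPS = frozenset("MIDX=")


@dataclass(frozen=True)
class ReadClipStats:
    """Per-read soft-clip geometry extracted from the CIGAR string."""

    contig: str
    start: int  # 0-based alignment start
    aligned_bases: int  # M/=/X/I/D op lengths summed
    left_clip: int  # soft-clipped bases 5' of the alignment
    right_clip: int  # soft-clipped bases 3' of the alignment

    @property
    def total_clip(self) -> int:
        return self.left_clip + self.right_clip


def cigar_clip_stats(cigar: str, contig: str = "", start: int = 0) -> ReadClipStats:
    """Parse a CIGAR string into :class:`ReadClipStats`.

    Soft clips are taken from the ends of the CIGAR (leading/trailing hard
    clips are skipped when locating them, per the SAM spec ordering); aligned
    bases sum the lengths of M, =, X, I and D operations.
    """
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{c}" for n, c in ops) != cigar:
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    lengths = [(int(n), c) for n, c in ops]
    aligned = sum(n for n, c in lengths if c in _ALIGNED_OPS)
    if aligned <= 0:
        raise ValueError(f"CIGAR {cigar!r} has no aligned bases")

    def end_clip(seq: Sequence[tuple[int, str]]) -> int:
        for n, c in seq:
            if c == "H":
                continue
            return n if c == "S" else 0
        return 0

    return ReadClipStats(
        contig=contig,
        start=start,
        aligned_bases=aligned,
        left_clip=end_clip(lengths),
        right_clip=end_clip(lengths[::-1]),
    )


def window_statistics(
    reads: Sequence[ReadClipStats],
) -> tuple[float, float, float]:
    """Compute (C, S, P) over the reads assigned to one window.

    Degenerate inputs return zeros: C is 0 when there are no aligned bases,
    S is 0 with fewer than two reads, P is 0 when no read is clipped. S is the
    population variance of ``left − right`` over *all* reads in the window
    (unclipped reads contribute 0). Reads clipped equally on both sides count
    in P's denominator but on neither side.
    """
    if not reads:
        return 0.0, 0.0, 0.0
    total_clip = sum(r.total_clip for r in reads)
    total_aligned = sum(r.aligned_bases for r in reads)
    c = total_clip / total_aligned if total_aligned > 0 else 0.0

    diffs = np.array([r.left_clip - r.right_clip for r in reads], dtype=float)
    s = float(np.var(diffs)) if len(diffs) >= 2 else 0.0

    n_left = sum(1 for r in reads if r.total_clip > 0 and r.left_clip > r.right_clip)
    n_right = sum(1 for r in reads if r.total_clip > 0 and r.right_clip > r.left_clip)
    n_tied = sum(1 for r in reads if r.total_clip > 0 and r.left_clip == r.right_clip)
    n_clipped = n_left + n_right + n_tied
    p = abs(n_left - n_right) / n_clipped if n_clipped > 0 else 0.0
    return c, s, p


def switch_index(c: float, s: float, p: float) -> float:
    """Switch-error risk index: C * (1 + P)^2 * S."""
    return c * (1.0 + p) ** 2 * s


def _read_stats_iter(
    alignments: str | Path,
    include_supplementary: bool,
) -> tuple[dict[str, int], list[ReadClipStats]]:
    stats: list[ReadClipStats] = []
    with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
        lengths = dict(zip(af.references or (), af.lengths or ()))
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary:
                continue
            if read.is_supplementary and not include_supplementary:
                continue
            if not read.cigarstring:
                continue
            stats.append(
                cigar_clip_stats(
                    read.cigarstring, read.reference_name, read.reference_start
                )
            )
    return lengths, stats


def switch_error_scan(
    alignments: str | Path,
    window: int = 10_000,
    step: int | None = None,
    include_supplementary: bool = False,
    min_clip: int = 1,
) -> pd.DataFrame:
    """Scan an alignment file and compute per-window switch-error risk.

    Windows of ``window`` bp tile each reference contig every ``step`` bp
    (default window/2, i.e. half-overlapping). Each primary mapped read is
    assigned to the single window whose start is the largest window start at
    or before the read's alignment start; secondary and unmapped records are
    always excluded, supplementary records by default. Side clips shorter
    than ``min_clip`` bases are ignored.

    Returns one row per window per contig with columns
    ``contig, win_start, win_end, n_reads, n_clipped, C, S, P, index``
    (coordinates 0-based half-open). An alignment file with no reference
    contigs yields an empty table.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    step = step if step is not None else max(window // 2, 1)
    if step <= 0:
        raise ValueError("step must be positive")
    lengths, stats = _read_stats_iter(Path(alignments), include_supplementary)

    if min_clip > 1:
        stats = [
            ReadClipStats(
                r.contig,
                r.start,
                r.aligned_bases,
                r.left_clip if r.left_clip >= min_clip else 0,
                r.right_clip if r.right_clip >= min_clip else 0,
            )
            for r in stats
        ]

    by_window: dict[tuple[str, int], list[ReadClipStats]] = {}
    for r in stats:
        clen = lengths.get(r.contig)
        win_start = (r.start // step) * step
        if clen is not None:
            win_start = min(win_start, _last_window_start(clen, window, step))
        by_window.setdefault((r.contig, win_start), []).append(r)

    rows = []
    for contig in sorted(lengths):
        clen = lengths[contig]
        for win_start in range(0, _last_window_start(clen, window, step) + 1, step):
            win_end = min(win_start + window, clen)
            reads = by_window.get((contig, win_start), [])
            c, s, p = window_statistics(reads)
            rows.append(
                {
                    "contig": contig,
                    "win_start": win_start,
                    "win_end": win_end,
                    "n_reads": len(reads),
                    "n_clipped": sum(1 for r in reads if r.total_clip > 0),
                    "C": c,
                    "S": s,
                    "P": p,
                    "index": switch_index(c, s, p),
                }
            )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def _last_window_start(contig_length: int, window: int, step: int) -> int:
    """Start of the final tiling window on a contig of the given length."""
    if contig_length <= window:
        return 0
    return ((contig_length - 1) // step) * step


def write_bedgraph(windows: pd.DataFrame, path: str | Path) -> None:
    """Write the index column of a window table as a bedGraph track."""
    windows[["contig", "win_start", "win_end", "index"]].to_csv(
        path, sep="\t", index=False, header=False
    )
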