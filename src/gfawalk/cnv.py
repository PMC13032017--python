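"""Gene copy-number uncertainty across alternative assembly paths.

Given per-unitig counts of a feature of interest (e.g. intact antifreeze
protein genes in a tandem array), each candidate contig's copy number is the
sum of counts over the unitigs on its path. Across all paths of a haplotype,
the spread of those copy numbers quantifies how much of an apparent CNV could
be an assembly artifact:

* margin of error = max − min copy number over all paths,
* percent uncertainty = 100 · margin / max (0 when max is 0),
* median copy number over the multiset of per-path values (paths counted
  with multiplicity).

When a region's haplotypes cannot be resolved (interconnected paths through
the bubble), a single "unresolved" record over *all* paths through the region
replaces the two per-haplotype records.
"""

from __future__ import annotations

import statistics
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .graph_io import AssemblyGraph, reverse_complement
from .paths import (
    DEFAULT_MAX_PATHS,
    HaplotypeSpec,
    OrientedPath,
    classify_resolution,
    enumerate_paths,
    phased_paths,
)

__all__ = [
    "path_copy_number",
    "uncertainty_report",
    "region_uncertainty",
    "count_motif_copies",
    "read_counts_tsv",
    "write_report_tsv",
]

REPORT_COLUMNS = [
    "record",
    "resolution",
    "n_paths",
    "min",
    "max",
    "margin",
    "percent_uncertainty",
    "median",
]


def read_counts_tsv(path: str | Path) -> dict[str, int]:
    """Read a two-column (unitig_id, copies) TSV; a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("counts TSV needs two columns: unitig_id, copies")
    # tolerate a header row by dropping a first row whose count is non-numeric
    if not df.iloc[0, 1].lstrip("-").isdigit():
        df = df.iloc[1:]
    counts = {}
    for uid, c in zip(df.iloc[:, 0], df.iloc[:, 1]):
        c = int(c)
        if c < 0:
            raise ValueError(f"negative copy count for unitig {uid!r}")
        counts[str(uid)] = c
    return counts


def path_copy_number(path: OrientedPath, counts: Mapping[str, int]) -> int:
    """Sum feature counts over a path's unitigs (orientation-independent).

    Unitigs missing from ``counts`` contribute 0 with a warning.
    """
    missing = [u for u in path.ids if u not in counts]
    if missing:
        warnings.warn(
            f"{len(missing)} path unitig(s) absent from counts (treated as 0): "
            f"{missing[:5]}",
            stacklevel=2,
        )
    return sum(counts.get(u, 0) for u in path.ids)


def _record(name: str, resolution: str, values: Sequence[int]) -> dict:
    if not values:
        raise ValueError(f"record {name!r}: at least one path is required")
    lo, hi = min(values), max(values)
    margin = hi - lo
    percent = round(100.0 * margin / hi, 2) if hi > 0 else 0.0
    return {
        "record": name,
        "resolution": resolution,
        "n_paths": len(values),
        "min": lo,
        "max": hi,
        "margin": margin,
        "percent_uncertainty": percent,
        "median": float(statistics.median(values)),
    }


def uncertainty_report(
    paths_by_record: Mapping[str, Sequence[OrientedPath | int]],
    counts: Mapping[str, int] | None = None,
    resolution: str = "resolved",
) -> pd.DataFrame:
    """Summarize copy-number uncertainty per record (haplotype or region).

    ``paths_by_record`` maps a record name (e.g. ``hap1``) to its paths, or
    directly to precomputed per-path copy numbers. Returns one row per record
    with min/max/margin/percent-uncertainty/median; percent uncertainty is the
    margin divided by the maximum possible copy number of that record, as a
    percentage rounded to two decimals.
    """
    rows = []
    for name, items in paths_by_record.items():
        values = [
            path_copy_number(item, counts or {})
            if isinstance(item, OrientedPath)
            else int(item)
            for item in items
        ]
        rows.append(_record(name, resolution, values))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def region_uncertainty(
    graph: AssemblyGraph,
    spec: HaplotypeSpec,
    counts: Mapping[str, int],
    max_paths: int = DEFAULT_MAX_PATHS,
    start_orient: str | None = None,
) -> pd.DataFrame:
    """Full per-region workflow: classify resolution, enumerate, summarize.

    Resolved regions yield one record per haplotype (all paths through that
    haplotype's unitigs plus shared unitigs). Unresolved regions — where paths
    interconnect the two haplotype sides of the bubble — yield a single record
    over all unrestricted paths through the region.
    """
    unknown = set(counts) - set(graph.unitigs)
    if unknown:
        raise KeyError(
            f"counts name unitigs absent from the graph: {sorted(unknown)[:5]}"
        )
    resolution = classify_resolution(
        graph, spec, max_paths=max_paths, start_orient=start_orient
    )
    if resolution == "unresolved":
        all_paths = enumerate_paths(
            graph,
            spec.start_id,
            spec.end_id,
            max_paths=max_paths,
            start_orient=start_orient,
            label="unresolved",
        )
        return uncertainty_report(
            {"unresolved": all_paths}, counts, resolution="unresolved"
        )
    hap1, hap2 = phased_paths(
        graph, spec, max_paths=max_paths, start_orient=start_orient
    )
    return uncertainty_report({"hap1": hap1, "hap2": hap2}, counts)


def write_report_tsv(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)


def count_motif_copies(
    sequence: str, motif: str, min_identity: float = 1.0
) -> int:
    """Count non-overlapping motif occurrences on either strand.

    A toy stand-in for protein-to-genome gene annotation: scans left to right
    and greedily counts windows matching the motif (or its reverse complement)
    at identity >= ``min_identity``, skipping the motif length after a hit so
    occurrences never overlap.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not 0.0 < min_identity <= 1.0:
        raise ValueError("min_identity must be in (0, 1]")
    seq = sequence.upper()
    fwd = motif.upper()
    rev = reverse_complement(fwd)
    k = len(fwd)
    max_mismatch = int((1.0 - min_identity) * k)

    def matches(window: str) -> bool:
        for target in (fwd, rev):
            mm = 0
            for a, b in zip(window, target):
                if a != b:
                    mm += 1
                    if mm > max_mismatch:
                        break
            else:
                return True
        return False

    n = 0
    i = 0
    limit = len(seq) - k
    while i <= limit:
        if max_mismatch == 0:
            if seq.startswith(fwd, i) or seq.startswith(rev, i):
                n += 1
                i += k
                continue
        elif matches(seq[i : i + k]):
            n += 1
            i += k
            continue
        i += 1
    return n
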