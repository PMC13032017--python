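"""Exhaustive enumeration of contig paths through a raw unitig graph.

A raw unitig graph (e.g. hifiasm's ``r_utg`` GFA) retains every alternative
unitig at heterozygous bubbles and every low-support small bubble that later
assembly stages would pop or purge. Each directed, acyclic path between the
5'-most and 3'-most unitigs of a region is therefore one possible contig the
assembler could have produced. Enumerating all of them bounds the assembly
uncertainty of the region instead of trusting the single path the assembler
happened to choose.

Paths are *unitig-ID-simple*: a unitig may appear at most once in a path, in
either orientation. This encodes the rule that no assembly path loops through
a unitig multiple times and automatically excludes alternate unitigs of the
same bubble from a single path (a path committed to one branch cannot rejoin
the other without revisiting a flanking unitig). Traversal is bidirected:
from state ``(u, o)`` the successors are the oriented links materialized by
:class:`~gfawalk.graph_io.AssemblyGraph`, which include reverse-complement
duals of every GFA L record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .graph_io import AssemblyGraph, reverse_complement

__all__ = [
    "OrientedPath",
    "HaplotypeSpec",
    "PathExplosionError",
    "DEFAULT_MAX_PATHS",
    "enumerate_paths",
    "phased_paths",
    "classify_resolution",
    "path_to_sequence",
    "write_path_fastas",
    "genome_wide_path_counts",
]

#: Cap on the number of enumerated paths. The tool is meant for regions with
#: up to hundreds of alternative contigs per haplotype; the cap guards the
#: exponential worst case of dense graphs.
DEFAULT_MAX_PATHS = 100_000


class PathExplosionError(RuntimeError):
    """Raised when the number of paths exceeds the ``max_paths`` cap."""

    def __init__(self, start_id: str, end_id: str, max_paths: int) -> None:
        super().__init__(
            f"more than {max_paths} unitig-simple paths between "
            f"{start_id!r} and {end_id!r}; raise max_paths to enumerate anyway"
        )
        self.max_paths = max_paths


@dataclass(frozen=True)
class OrientedPath:
    """An ordered walk of (unitig ID, orientation) steps — one candidate contig."""

    steps: tuple[tuple[str, str], ...]
    haplotype_label: str = "unphased"

    def __post_init__(self) -> None:
        ids = [u for u, _ in self.steps]
        if len(set(ids)) != len(ids):
            raise ValueError("a unitig may appear only once per path")
        for _, o in self.steps:
            if o not in "+-":
                raise ValueError("orientation must be '+' or '-'")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(u for u, _ in self.steps)

    def __len__(self) -> int:
        return len(self.steps)

    def __str__(self) -> str:
        return ",".join(f"{u}{o}" for u, o in self.steps)

    def relabel(self, label: str) -> "OrientedPath":
        return OrientedPath(self.steps, label)


@dataclass(frozen=True)
class HaplotypeSpec:
    """A phased region: flanking start/end unitigs plus two haplotype ID sets.

    Unitig IDs listed in neither set are treated as shared (homozygous)
    sequence available to both haplotype assemblies.
    """

    start_id: str
    end_id: str
    hap1_ids: frozenset[str]
    hap2_ids: frozenset[str]

    def __init__(
        self,
        start_id: str,
        end_id: str,
        hap1_ids: Iterable[str],
        hap2_ids: Iterable[str],
    ) -> None:
        object.__setattr__(self, "start_id", start_id)
        object.__setattr__(self, "end_id", end_id)
        object.__setattr__(self, "hap1_ids", frozenset(hap1_ids))
        object.__setattr__(self, "hap2_ids", frozenset(hap2_ids))
        overlap = self.hap1_ids & self.hap2_ids
        if overlap:
            raise ValueError(
                f"haplotype unitig sets overlap: {sorted(overlap)[:5]}"
            )

    def validate(self, graph: AssemblyGraph) -> None:
        for uid in (self.start_id, self.end_id):
            if uid not in graph:
                raise KeyError(f"flanking unitig {uid!r} not in graph")
        unknown = (self.hap1_ids | self.hap2_ids) - set(graph.unitigs)
        if unknown:
            raise KeyError(
                f"haplotype list names unknown unitigs: {sorted(unknown)[:5]}"
            )


def _dfs_enumerate(
    graph: AssemblyGraph,
    start_id: str,
    start_orient: str,
    end_id: str,
    allowed: frozenset[str] | None,
    max_paths: int,
) -> list[tuple[tuple[str, str], ...]]:
    """Depth-first enumeration of ID-simple oriented walks, children visited in
    lexicographic (id, orient) order so output is deterministic."""
    paths: list[tuple[tuple[str, str], ...]] = []
    path: list[tuple[str, str]] = [(start_id, start_orient)]
    visited: set[str] = {start_id}

    def visit(u: str, o: str) -> None:
        for v, vo, _ in graph.successors(u, o):
            if v in visited:
                continue
            if v == end_id:
                if len(paths) >= max_paths:
                    raise PathExplosionError(start_id, end_id, max_paths)
                paths.append(tuple(path) + ((v, vo),))
                continue
            if allowed is not None and v not in allowed:
                continue
            visited.add(v)
            path.append((v, vo))
            visit(v, vo)
            path.pop()
            visited.remove(v)

    visit(start_id, start_orient)
    return paths


def enumerate_paths(
    graph: AssemblyGraph,
    start_id: str,
    end_id: str,
    allowed: Iterable[str] | None = None,
    max_paths: int = DEFAULT_MAX_PATHS,
    start_orient: str | None = None,
    label: str = "unphased",
) -> list[OrientedPath]:
    """Enumerate every directed, acyclic path from ``start_id`` to ``end_id``.

    Parameters
    ----------
    allowed
        If given, interior unitigs must belong to this set (the flanking
        start/end unitigs are exempt). Used to restrict enumeration to one
        haplotype's unitigs plus shared sequence.
    max_paths
        Hard cap; exceeding it raises :class:`PathExplosionError`.
    start_orient
        Pin the orientation of the start unitig. By default ``+`` is tried
        first and ``-`` only if no ``+`` path exists.

    Returns
    -------
    list of OrientedPath, ordered lexicographically by step sequence.
    """
    if max_paths < 1:
        raise ValueError("max_paths must be >= 1")
    for uid in (start_id, end_id):
        if uid not in graph:
            raise KeyError(f"unitig {uid!r} not in graph")
    if start_id == end_id:
        warnings.warn(
            f"start and end unitig are both {start_id!r}; returning the "
            "zero-length path",
            stacklevel=2,
        )
        return [OrientedPath(((start_id, start_orient or "+"),), label)]

    allowed_set = frozenset(allowed) if allowed is not None else None
    orients = (start_orient,) if start_orient else ("+", "-")
    raw: list[tuple[tuple[str, str], ...]] = []
    for o in orients:
        raw = _dfs_enumerate(graph, start_id, o, end_id, allowed_set, max_paths)
        if raw:
            break
    raw.sort()
    return [OrientedPath(steps, label) for steps in raw]


def phased_paths(
    graph: AssemblyGraph,
    spec: HaplotypeSpec,
    max_paths: int = DEFAULT_MAX_PATHS,
    start_orient: str | None = None,
) -> tuple[list[OrientedPath], list[OrientedPath]]:
    """Enumerate all possible contigs of each haplotype through a phased region.

    Each haplotype's paths may use its own unitigs plus any unitig listed in
    neither haplotype set (shared/homozygous unitigs present in both haplotype
    assemblies). Returns ``(hap1_paths, hap2_paths)`` labelled accordingly; an
    empty result for a haplotype emits a warning, not an error.
    """
    spec.validate(graph)
    shared = frozenset(graph.unitigs) - spec.hap1_ids - spec.hap2_ids
    out: list[list[OrientedPath]] = []
    for name, hap_ids in (("hap1", spec.hap1_ids), ("hap2", spec.hap2_ids)):
        paths = enumerate_paths(
            graph,
            spec.start_id,
            spec.end_id,
            allowed=hap_ids | shared,
            max_paths=max_paths,
            start_orient=start_orient,
            label=name,
        )
        if not paths:
            warnings.warn(f"no {name} path from {spec.start_id!r} to "
                          f"{spec.end_id!r}", stacklevel=2)
        out.append(paths)
    return out[0], out[1]


def classify_resolution(
    graph: AssemblyGraph,
    spec: HaplotypeSpec,
    max_paths: int = DEFAULT_MAX_PATHS,
    start_orient: str | None = None,
) -> str:
    """Decide whether a phased region's haplotypes can be resolved.

    The region is ``unresolved`` iff some unrestricted start-to-end path mixes
    interior unitigs from both haplotype lists — interconnected assembly paths
    through the bubble prevent the haplotypes from being distinguished.
    """
    spec.validate(graph)
    flanks = {spec.start_id, spec.end_id}
    for path in enumerate_paths(
        graph, spec.start_id, spec.end_id, max_paths=max_paths,
        start_orient=start_orient,
    ):
        interior = set(path.ids) - flanks
        if interior & spec.hap1_ids and interior & spec.hap2_ids:
            return "unresolved"
    return "resolved"


def path_to_sequence(graph: AssemblyGraph, path: OrientedPath) -> str:
    """Reconstruct the contig sequence of a path.

    The first unitig's oriented sequence is extended by each following
    oriented sequence with its link overlap trimmed, so the result length is
    the sum of unitig lengths minus the sum of link overlaps. A ``-`` step
    contributes the reverse complement of the unitig sequence.
    """
    if not path.steps:
        raise ValueError("empty path")

    def oriented(uid: str, orient: str) -> str:
        unitig = graph.unitigs[uid]
        if unitig.sequence is None:
            raise ValueError(
                f"unitig {uid!r} has no sequence ('*' S record); cannot "
                "reconstruct the contig"
            )
        return unitig.sequence if orient == "+" else reverse_complement(
            unitig.sequence
        )

    u0, o0 = path.steps[0]
    parts = [oriented(u0, o0)]
    prev = (u0, o0)
    for u, o in path.steps[1:]:
        ov = graph.overlap(prev[0], prev[1], u, o)
        seq = oriented(u, o)
        if ov >= len(seq) or ov >= graph.unitigs[prev[0]].length:
            raise ValueError(
                f"overlap {ov} between {prev[0]} and {u} is not shorter than "
                "both unitigs"
            )
        parts.append(seq[ov:])
        prev = (u, o)
    return "".join(parts)


def write_path_fastas(
    graph: AssemblyGraph,
    paths: Sequence[OrientedPath],
    outdir: str | Path,
    name: str,
) -> pd.DataFrame:
    """Export one FASTA per path plus a summary table.

    Files are named ``<name>_<hap>_path<k>.fasta`` with ``k`` 1-based and
    zero-padded to 4 digits; each header is
    ``<name>|<hap>|path<k>|unitigs=u1+,u2-,...|len=N``. Returns the summary
    DataFrame (path_id, haplotype, n_unitigs, length).
    """
    from .graph_io import write_fasta  # local import: avoids cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counters: dict[str, int] = {}
    rows = []
    for path in paths:
        hap = path.haplotype_label
        counters[hap] = counters.get(hap, 0) + 1
        k = counters[hap]
        seq = path_to_sequence(graph, path)
        path_id = f"path{k:04d}"
        header = f"{name}|{hap}|{path_id}|unitigs={path}|len={len(seq)}"
        write_fasta([(header, seq)], outdir / f"{name}_{hap}_{path_id}.fasta")
        rows.append(
            {
                "path_id": path_id,
                "haplotype": hap,
                "n_unitigs": len(path),
                "length": len(seq),
            }
        )
    return pd.DataFrame(rows, columns=["path_id", "haplotype", "n_unitigs", "length"])


def _tips(graph: AssemblyGraph, ids: Iterable[str]) -> list[str]:
    """Unitigs with no oriented successor on at least one side (chain ends)."""
    return sorted(
        u for u in ids
        if not graph.successors(u, "+") or not graph.successors(u, "-")
    )


def genome_wide_path_counts(
    graph: AssemblyGraph, max_paths: int = DEFAULT_MAX_PATHS
) -> pd.DataFrame:
    """Count assembly paths between chain ends across the whole graph.

    For every weakly connected component, tip unitigs (those missing an
    oriented successor on one side) are paired and the number of ID-simple
    oriented paths between each pair is counted. Single-unitig components
    report a count of 1; a component whose path count exceeds ``max_paths``
    reports the sentinel ``">{max_paths}"`` instead of failing; a cyclic
    component with no tips reports a single zero-count row.

    Returns a DataFrame with columns ``component``, ``source``, ``sink``,
    ``n_paths`` (object dtype: int or sentinel string).
    """
    undirected = nx.Graph()
    undirected.add_nodes_from(graph.unitigs)
    for l in graph.links:
        undirected.add_edge(l.from_id, l.to_id)

    rows: list[tuple[int, str, str, object]] = []
    components = sorted(nx.connected_components(undirected), key=min)
    for comp_id, comp in enumerate(components):
        if len(comp) == 1:
            (u,) = comp
            rows.append((comp_id, u, u, 1))
            continue
        tips = _tips(graph, comp)
        if len(tips) < 2:
            rows.append((comp_id, min(comp), min(comp), 0))
            continue
        for i, src in enumerate(tips):
            for snk in tips[i + 1:]:
                try:
                    n: object = len(
                        enumerate_paths(graph, src, snk, max_paths=max_paths)
                    )
                except PathExplosionError:
                    n = f">{max_paths}"
                rows.append((comp_id, src, snk, n))
    return pd.DataFrame(rows, columns=["component", "source", "sink", "n_paths"])
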