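"""Reading and writing assembly graphs and sequences.

GFA1 segment (S) and link (L) records are loaded into an :class:`AssemblyGraph`,
a bidirected string graph: every link also implies its reverse-complement
traversal, and both directions are materialized so traversal code never has to
reason about link duals. Several assembler dialects (hifiasm raw unitig graphs,
Verkko, Shasta, minigraph) are recognized, but all are reduced to the same
uniform representation; records other than S and L (A, P, W lines, headers)
are tolerated and skipped.

Only exact-match overlaps are supported: overlap CIGARs must be ``<int>M``,
``0M`` or ``*``. Anything containing I/D/X operations is rejected, because
downstream path-to-sequence concatenation trims overlaps as exact duplicates.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Unitig",
    "Link",
    "AssemblyGraph",
    "GfaParseError",
    "UnsupportedOverlapError",
    "parse_gfa",
    "write_gfa",
    "reverse_complement",
    "write_fasta",
]


class GfaParseError(ValueError):
    """Raised for malformed S/L records; message names the offending line."""


class UnsupportedOverlapError(GfaParseError):
    """Raised when a link overlap CIGAR is not an exact match (``<int>M``)."""


_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBTGCANYRSWMKVHDB",
)
_DNA_RE = re.compile(r"^[ACGTNRYSWKMBDHVacgtnryswkmbdhv]*$")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (IUPAC alphabet), returned uppercase."""
    if not _DNA_RE.match(seq):
        bad = next(c for c in seq if not _DNA_RE.match(c))
        raise ValueError(f"non-IUPAC character in sequence: {bad!r}")
    return seq.translate(_COMPLEMENT)[::-1].upper()


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


@dataclass(frozen=True)
class Unitig:
    """A unitig: a high-confidence assembly unit (node of the string graph)."""

    id: str
    sequence: str | None
    length: int
    depth: float | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"unitig {self.id}: length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"unitig {self.id}: length {self.length} != sequence length "
                f"{len(self.sequence)}"
            )
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"unitig {self.id}: negative depth")


@dataclass(frozen=True)
class Link:
    """An oriented overlap between two unitig ends (edge of the string graph)."""

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str
    overlap: int

    def __post_init__(self) -> None:
        if self.from_orient not in "+-" or self.to_orient not in "+-":
            raise ValueError("link orientation must be '+' or '-'")
        if self.overlap < 0:
            raise ValueError("negative overlap")

    def dual(self) -> "Link":
        """The reverse-complement traversal implied by this link."""
        return Link(
            self.to_id,
            _flip(self.to_orient),
            self.from_id,
            _flip(self.from_orient),
            self.overlap,
        )


class AssemblyGraph:
    """An in-memory raw unitig graph: unitigs plus bidirected links.

    Both each L record and its reverse-complement dual are materialized into
    the oriented adjacency used by path enumeration; ``links`` retains only
    the records as written, so a parse -> write -> parse round trip is exact.
    """

    def __init__(
        self,
        unitigs: Mapping[str, Unitig],
        links: Sequence[Link],
        dialect: str = "generic",
    ) -> None:
        self.unitigs: dict[str, Unitig] = dict(unitigs)
        self.links: list[Link] = list(links)
        self.dialect = dialect
        self._adj: dict[tuple[str, str], list[tuple[str, str, int]]] = {}
        self._overlaps: dict[tuple[str, str, str, str], int] = {}
        for link in self.links:
            for l in (link, link.dual()):
                if l.from_id not in self.unitigs or l.to_id not in self.unitigs:
                    missing = l.from_id if l.from_id not in self.unitigs else l.to_id
                    raise GfaParseError(
                        f"link references unknown unitig {missing!r}"
                    )
                lmin = min(
                    self.unitigs[l.from_id].length, self.unitigs[l.to_id].length
                )
                if l.overlap >= lmin:
                    raise GfaParseError(
                        f"link {l.from_id}{l.from_orient}->{l.to_id}{l.to_orient}: "
                        f"overlap {l.overlap} >= shortest unitig length {lmin}"
                    )
                key = (l.from_id, l.from_orient)
                succ = (l.to_id, l.to_orient, l.overlap)
                bucket = self._adj.setdefault(key, [])
                if succ not in bucket:
                    bucket.append(succ)
                self._overlaps[
                    (l.from_id, l.from_orient, l.to_id, l.to_orient)
                ] = l.overlap
        for bucket in self._adj.values():
            bucket.sort()

    def successors(self, unitig_id: str, orient: str) -> list[tuple[str, str, int]]:
        """Oriented successors of (unitig, orient): (id, orient, overlap) triples,
        sorted lexicographically ('+' sorts before '-')."""
        return self._adj.get((unitig_id, orient), [])

    def overlap(self, u: str, uo: str, v: str, vo: str) -> int:
        """Overlap length of the oriented link (u,uo) -> (v,vo)."""
        try:
            return self._overlaps[(u, uo, v, vo)]
        except KeyError:
            raise KeyError(f"no link {u}{uo} -> {v}{vo} in graph") from None

    def __len__(self) -> int:
        return len(self.unitigs)

    def __contains__(self, unitig_id: str) -> bool:
        return unitig_id in self.unitigs

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"AssemblyGraph({len(self.unitigs)} unitigs, {len(self.links)} links, "
            f"dialect={self.dialect!r})"
        )


_OVERLAP_RE = re.compile(r"^(\d+)M$")


def _parse_overlap(cigar: str, lineno: int) -> int:
    if cigar == "*":
        return 0
    m = _OVERLAP_RE.match(cigar)
    if m:
        return int(m.group(1))
    raise UnsupportedOverlapError(
        f"line {lineno}: overlap CIGAR {cigar!r} is not an exact match; only "
        "'<int>M', '0M' or '*' overlaps are supported"
    )


def _parse_tags(fields: Iterable[str], lineno: int) -> dict[str, str]:
    tags = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) != 3:
            raise GfaParseError(f"line {lineno}: malformed tag {f!r}")
        tags[parts[0]] = parts[2]
    return tags


def _depth_from_tags(tags: Mapping[str, str], length: int) -> float | None:
    # precedence rd:i > dp:f > DP:f > mean from read count RC:i
    for key in ("rd", "dp", "DP"):
        if key in tags:
            return float(tags[key])
    if "RC" in tags and length > 0:
        return float(tags["RC"]) / length
    return None


def _detect_dialect(
    ids: Iterable[str], s_tags: Iterable[Mapping[str, str]]
) -> str:
    ids = list(ids)
    tag_keys: set[str] = set()
    for t in s_tags:
        tag_keys.update(t)
    if "SN" in tag_keys and "SO" in tag_keys:
        return "minigraph"
    if ids and all(re.match(r"^(utg|ptg)\d+[lc]$", i) for i in ids):
        return "hifiasm"
    if ids and all("utig" in i or i.startswith("piece") for i in ids):
        return "verkko"
    if ids and all(i.isdigit() for i in ids):
        return "shasta"
    return "generic"


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_gfa(path: str | Path, dialect: str | None = None) -> AssemblyGraph:
    """Parse a GFA1 file into an :class:`AssemblyGraph`.

    S and L records are loaded; all other record types (headers, A, P, W, ...)
    are skipped. Sequences are stored uppercase; a ``*`` sequence yields a
    unitig with ``sequence=None`` and length taken from the ``LN:i`` tag.
    Read depth is read from the first present of ``rd:i``, ``dp:f``, ``DP:f``,
    or derived as ``RC:i / length``. The dialect is auto-detected from ID
    patterns and tags when not given.
    """
    unitigs: dict[str, Unitig] = {}
    raw_links: list[tuple[int, str, str, str, str, int]] = []
    s_tags: list[dict[str, str]] = []

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line[0] not in "SL":
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                if len(fields) < 3:
                    raise GfaParseError(
                        f"line {lineno}: S record needs at least 3 fields"
                    )
                sid, seq = fields[1], fields[2]
                tags = _parse_tags(fields[3:], lineno)
                s_tags.append(tags)
                if sid in unitigs:
                    raise GfaParseError(f"line {lineno}: duplicate segment {sid!r}")
                if seq == "*":
                    if "LN" not in tags:
                        raise GfaParseError(
                            f"line {lineno}: segment {sid!r} has no sequence and "
                            "no LN:i tag"
                        )
                    sequence, length = None, int(tags["LN"])
                else:
                    if not _DNA_RE.match(seq):
                        raise GfaParseError(
                            f"line {lineno}: segment {sid!r} has a non-IUPAC "
                            "sequence"
                        )
                    sequence = seq.upper()
                    length = len(sequence)
                try:
                    unitigs[sid] = Unitig(
                        sid, sequence, length, _depth_from_tags(tags, length)
                    )
                except ValueError as exc:
                    raise GfaParseError(f"line {lineno}: {exc}") from exc
            elif fields[0] == "L":
                if len(fields) < 6:
                    raise GfaParseError(
                        f"line {lineno}: L record needs at least 6 fields"
                    )
                _, fr, fo, to, too, ov = fields[:6]
                if fo not in "+-" or too not in "+-":
                    raise GfaParseError(
                        f"line {lineno}: link orientation must be '+' or '-'"
                    )
                raw_links.append((lineno, fr, fo, to, too, _parse_overlap(ov, lineno)))

    links = []
    for lineno, fr, fo, to, too, ov in raw_links:
        if fr not in unitigs or to not in unitigs:
            missing = fr if fr not in unitigs else to
            raise GfaParseError(
                f"line {lineno}: link references unknown unitig {missing!r}"
            )
        links.append(Link(fr, fo, to, too, ov))

    if dialect is None:
        dialect = _detect_dialect(unitigs.keys(), s_tags)
    return AssemblyGraph(unitigs, links, dialect=dialect)


def write_gfa(graph: AssemblyGraph, path: str | Path) -> None:
    """Write a graph back out as GFA1 (S records, then the L records as parsed)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for u in graph.unitigs.values():
            seq = u.sequence if u.sequence is not None else "*"
            tags = [f"LN:i:{u.length}"]
            if u.depth is not None:
                tags.append(f"dp:f:{u.depth}")
            fh.write("\t".join(["S", u.id, seq, *tags]) + "\n")
        for l in graph.links:
            fh.write(
                f"L\t{l.from_id}\t{l.from_orient}\t{l.to_id}\t{l.to_orient}\t"
                f"{l.overlap}M\n"
            )


def write_fasta(
    records: Sequence[tuple[str, str]], path: str | Path, width: int = 80
) -> None:
    """Write (header, sequence) records as FASTA, wrapped to ``width`` columns.

    Headers must be unique; a duplicate raises ``ValueError``.
    """
    seen: set[str] = set()
    with open(path, "w") as fh:
        for header, seq in records:
            if header in seen:
                raise ValueError(f"duplicate FASTA header {header!r}")
            seen.add(header)
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
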