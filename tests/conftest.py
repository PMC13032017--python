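import random

import pytest

from gfawalk.graph_io import AssemblyGraph, Link, Unitig


def build_graph(segments, links, dialect="generic"):
    """Convenience graph builder.

    segments: iterable of (id, sequence) or (id, None, length) tuples.
    links: iterable of (from, from_orient, to, to_orient, overlap).
    """
    unitigs = {}
    for seg in segments:
        if len(seg) == 2:
            uid, seq = seg
            unitigs[uid] = Unitig(uid, seq, len(seq))
        else:
            uid, seq, length = seg
            unitigs[uid] = Unitig(uid, seq, length)
    return AssemblyGraph(
        unitigs, [Link(*l) for l in links], dialect=dialect
    )


def random_link_graph(rng: random.Random, max_unitigs: int = 12):
    """A random small bidirected graph for oracle-equivalence tests.

    Returns (graph, link_tuples, ids). Edge density is kept low enough that
    exhaustive enumeration stays tiny.
    """
    n = rng.randint(4, max_unitigs)
    ids = [f"u{i:02d}" for i in range(n)]
    m = rng.randint(n - 1, int(1.6 * n))
    seen = set()
    links = []
    for _ in range(m):
        f, t = rng.sample(ids, 2)
        fo, to = rng.choice("+-"), rng.choice("+-")
        if (f, fo, t, to) in seen:
            continue
        seen.add((f, fo, t, to))
        links.append((f, fo, t, to, 0))
    graph = build_graph([(u, None, rng.randint(10, 50)) for u in ids], links)
    return graph, [(f, fo, t, to) for f, fo, t, to, _ in links], ids


@pytest.fixture
def two_bubble_chain():
    """A+ -> {B1|B2}+ -> C+ -> {D1|D2}+ -> E+: two independent 2-branch
    bubbles between A and E (4 total paths), exact 2-base overlaps."""
    segs = [
        ("A", "ACGTACGTAC"),
        ("B1", "ACTTTTGGCA"),
        ("B2", "ACAAAACGCA"),
        ("C", "CATTGGCCAA"),
        ("D1", "AACCCCTTAA"),
        ("D2", "AAGGGGTTAA"),
        ("E", "AAGCGCGCGC"),
    ]
    links = [
        ("A", "+", "B1", "+", 2),
        ("A", "+", "B2", "+", 2),
        ("B1", "+", "C", "+", 2),
        ("B2", "+", "C", "+", 2),
        ("C", "+", "D1", "+", 2),
        ("C", "+", "D2", "+", 2),
        ("D1", "+", "E", "+", 2),
        ("D2", "+", "E", "+", 2),
    ]
    # sequences are hand-picked so each downstream 2-base prefix equals the
    # upstream 2-base suffix (exact-overlap consistency)
    return build_graph(segs, links)
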