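"""Independent brute-force oracle for oriented path enumeration.

Written directly from the definition, independently of the package's
traversal code: materialize every link and its reverse-complement dual into a
plain adjacency mapping, then recursively enumerate all walks from the start
to the end unitig in which no unitig ID recurs (in either orientation).
Intentionally naive — sets, tuples and recursion only — so it can serve as a
ground truth for the production enumerator on small graphs.
"""

from __future__ import annotations


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def oracle_adjacency(links):
    """links: iterable of (from_id, from_orient, to_id, to_orient) tuples."""
    adj: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for f, fo, t, to in links:
        adj.setdefault((f, fo), set()).add((t, to))
        adj.setdefault((t, _flip(to)), set()).add((f, _flip(fo)))
    return adj


def oracle_paths(links, start, end, allowed=None, start_orient=None):
    """All ID-simple oriented walks from start to end, as a set of tuples.

    Start orientation: '+' first, '-' only when no '+' walk exists, unless
    pinned. Interior nodes must lie in `allowed` when given.
    """
    adj = oracle_adjacency(links)
    results: set[tuple[tuple[str, str], ...]] = set()

    def walk(node, used, path):
        for nxt in adj.get(node, ()):
            nid, _ = nxt
            if nid in used:
                continue
            if nid == end:
                results.add(path + (nxt,))
                continue
            if allowed is not None and nid not in allowed:
                continue
            walk(nxt, used | {nid}, path + (nxt,))

    orients = [start_orient] if start_orient else ["+", "-"]
    for o in orients:
        first = (start, o)
        walk(first, {start}, (first,))
        if results:
            break
    return results


def oracle_is_unresolved(links, start, end, hap1, hap2):
    """True iff some unrestricted walk mixes interior IDs from both sets."""
    hap1, hap2 = set(hap1), set(hap2)
    for path in oracle_paths(links, start, end):
        interior = {u for u, _ in path} - {start, end}
        if interior & hap1 and interior & hap2:
            return True
    return False
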