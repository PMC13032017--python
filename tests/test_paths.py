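import random
import warnings

import pytest

from conftest import build_graph, random_link_graph
from oracle_paths import oracle_is_unresolved, oracle_paths

from gfawalk.graph_io import reverse_complement, write_gfa, parse_gfa
from gfawalk.paths import (
    HaplotypeSpec,
    OrientedPath,
    PathExplosionError,
    classify_resolution,
    enumerate_paths,
    genome_wide_path_counts,
    path_to_sequence,
    phased_paths,
    write_path_fastas,
)


def as_step_sets(paths):
    return {p.steps for p in paths}


class TestEnumerate:
    def test_linear_chain_single_path(self):
        g = build_graph(
            [("A", None, 10), ("B", None, 10), ("C", None, 10)],
            [("A", "+", "B", "+", 0), ("B", "+", "C", "+", 0)],
        )
        paths = enumerate_paths(g, "A", "C")
        assert [p.steps for p in paths] == [
            ((("A", "+"), ("B", "+"), ("C", "+")))
        ]

    def test_two_independent_bubbles_multiply(self, two_bubble_chain):
        paths = enumerate_paths(two_bubble_chain, "A", "E")
        assert len(paths) == 4
        # lexicographic, deterministic ordering
        assert [str(p) for p in paths] == sorted(str(p) for p in paths)

    def test_allowed_set_restricts_interior(self, two_bubble_chain):
        paths = enumerate_paths(
            two_bubble_chain, "A", "E", allowed={"B1", "C", "D1", "D2"}
        )
        assert len(paths) == 2
        assert all("B2" not in p.ids for p in paths)

    def test_start_equals_end_returns_trivial_path(self, two_bubble_chain):
        with pytest.warns(UserWarning, match="zero-length"):
            paths = enumerate_paths(two_bubble_chain, "A", "A")
        assert [p.steps for p in paths] == [((("A", "+"),))]

    def test_missing_endpoint_raises(self, two_bubble_chain):
        with pytest.raises(KeyError):
            enumerate_paths(two_bubble_chain, "A", "nope")

    def test_explosion_cap(self, two_bubble_chain):
        with pytest.raises(PathExplosionError, match="more than 2"):
            enumerate_paths(two_bubble_chain, "A", "E", max_paths=2)

    def test_minus_orientation_fallback(self):
        # only traversal is A- -> B- (the dual of B+ -> A+)
        g = build_graph(
            [("A", None, 10), ("B", None, 10)], [("B", "+", "A", "+", 0)]
        )
        paths = enumerate_paths(g, "A", "B")
        assert paths[0].steps == (("A", "-"), ("B", "-"))

    def test_unitig_cannot_recur_in_opposite_orientation(self):
        # the only walk from X to C would be X+,A+,B+,A-,C+ — a palindromic
        # loop through A, forbidden even though the orientations differ
        g = build_graph(
            [("X", None, 10), ("A", None, 10), ("B", None, 10), ("C", None, 10)],
            [
                ("X", "+", "A", "+", 0),
                ("A", "+", "B", "+", 0),
                ("B", "+", "A", "-", 0),
                ("A", "-", "C", "+", 0),
            ],
        )
        assert enumerate_paths(g, "X", "C") == []

    def test_oracle_equivalence_on_random_graphs(self):
        rng = random.Random(20260919)
        checked = 0
        for _ in range(40):
            graph, links, ids = random_link_graph(rng)
            start, end = rng.sample(ids, 2)
            expected = oracle_paths(links, start, end)
            got = enumerate_paths(graph, start, end, max_paths=500_000)
            assert as_step_sets(got) == expected
            checked += 1
        assert checked == 40

    def test_determinism_identical_bytes_identical_order(
        self, tmp_path, two_bubble_chain
    ):
        p = tmp_path / "g.gfa"
        write_gfa(two_bubble_chain, p)
        runs = [
            [str(x) for x in enumerate_paths(parse_gfa(p), "A", "E")]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]


class TestPhased:
    @pytest.fixture
    def clean_bubble(self):
        return build_graph(
            [("A", None, 10), ("B1", None, 10), ("B2", None, 10), ("C", None, 10)],
            [
                ("A", "+", "B1", "+", 0),
                ("A", "+", "B2", "+", 0),
                ("B1", "+", "C", "+", 0),
                ("B2", "+", "C", "+", 0),
            ],
        )

    def test_single_haplotype_bubble(self, clean_bubble):
        spec = HaplotypeSpec("A", "C", {"B1"}, {"B2"})
        h1, h2 = phased_paths(clean_bubble, spec)
        assert len(h1) == len(h2) == 1
        assert h1[0].haplotype_label == "hap1"
        assert h1[0].ids == ("A", "B1", "C")
        assert h2[0].ids == ("A", "B2", "C")
        assert classify_resolution(clean_bubble, spec) == "resolved"

    def test_nested_small_bubble_on_hap1(self):
        # hap1 branch contains a small bubble (two alternatives), hap2 is plain
        g = build_graph(
            [(u, None, 10) for u in "A C X1a X1b Y1 Z1 B2".split()],
            [
                ("A", "+", "X1a", "+", 0),
                ("X1a", "+", "X1b", "+", 0),
                ("X1a", "+", "Y1", "+", 0),
                ("X1b", "+", "Z1", "+", 0),
                ("Y1", "+", "Z1", "+", 0),
                ("Z1", "+", "C", "+", 0),
                ("A", "+", "B2", "+", 0),
                ("B2", "+", "C", "+", 0),
            ],
        )
        spec = HaplotypeSpec("A", "C", {"X1a", "X1b", "Y1", "Z1"}, {"B2"})
        h1, h2 = phased_paths(g, spec)
        assert len(h1) == 2
        assert len(h2) == 1
        assert classify_resolution(g, spec) == "resolved"

    def test_overlapping_haplotype_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            HaplotypeSpec("A", "C", {"B1", "B2"}, {"B2"})

    def test_cross_link_makes_unresolved(self, clean_bubble):
        g = build_graph(
            [(u.id, None, u.length) for u in clean_bubble.unitigs.values()],
            [
                (l.from_id, l.from_orient, l.to_id, l.to_orient, l.overlap)
                for l in clean_bubble.links
            ]
            + [("B1", "+", "B2", "+", 0)],
        )
        spec = HaplotypeSpec("A", "C", {"B1"}, {"B2"})
        assert classify_resolution(g, spec) == "unresolved"

    def test_empty_haplotype_warns_not_errors(self, clean_bubble):
        # hap1 list names a unitig that cannot reach the end exclusively
        g = build_graph(
            [("A", None, 10), ("B1", None, 10), ("C", None, 10)],
            [("A", "+", "B1", "+", 0), ("B1", "+", "C", "+", 0)],
        )
        spec = HaplotypeSpec("A", "C", set(), {"B1"})
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            h1, h2 = phased_paths(g, spec)
        # hap1 may still route through shared unitigs; hap2 uses B1
        assert len(h2) == 1

    def test_classification_matches_oracle_on_random_graphs(self):
        rng = random.Random(777)
        for _ in range(30):
            graph, links, ids = random_link_graph(rng)
            start, end = rng.sample(ids, 2)
            others = [u for u in ids if u not in (start, end)]
            rng.shuffle(others)
            half = len(others) // 2
            hap1, hap2 = set(others[:half]), set(others[half:])
            spec = HaplotypeSpec(start, end, hap1, hap2)
            expected = (
                "unresolved"
                if oracle_is_unresolved(links, start, end, hap1, hap2)
                else "resolved"
            )
            assert classify_resolution(graph, spec, max_paths=500_000) == expected
            # phased enumeration agrees with the restricted oracle
            shared = set(ids) - hap1 - hap2
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                h1, h2 = phased_paths(graph, spec, max_paths=500_000)
            assert as_step_sets(h1) == oracle_paths(
                links, start, end, allowed=hap1 | shared
            )
            assert as_step_sets(h2) == oracle_paths(
                links, start, end, allowed=hap2 | shared
            )


class TestSequenceReconstruction:
    def test_two_base_overlap_concatenation(self):
        g = build_graph(
            [("A", "ACGTT"), ("B", "TTGCA")], [("A", "+", "B", "+", 2)]
        )
        (path,) = enumerate_paths(g, "A", "B")
        assert path_to_sequence(g, path) == "ACGTTGCA"

    def test_single_step_minus_is_reverse_complement(self):
        g = build_graph([("A", "AAGC")], [])
        path = OrientedPath((("A", "-"),))
        assert path_to_sequence(g, path) == "GCTT"

    def test_length_conservation(self, two_bubble_chain):
        g = two_bubble_chain
        for path in enumerate_paths(g, "A", "E"):
            seq = path_to_sequence(g, path)
            total = sum(g.unitigs[u].length for u in path.ids)
            overlaps = sum(
                g.overlap(*path.steps[i], *path.steps[i + 1])
                for i in range(len(path) - 1)
            )
            assert len(seq) == total - overlaps

    def test_missing_sequence_names_unitig(self):
        g = build_graph(
            [("A", "ACGTT"), ("B", None, 7)], [("A", "+", "B", "+", 0)]
        )
        (path,) = enumerate_paths(g, "A", "B")
        with pytest.raises(ValueError, match="'B'"):
            path_to_sequence(g, path)

    def test_export_names_and_headers(self, tmp_path, two_bubble_chain):
        paths = enumerate_paths(two_bubble_chain, "A", "E")
        summary = write_path_fastas(two_bubble_chain, paths, tmp_path, "arr")
        files = sorted(f.name for f in tmp_path.glob("*.fasta"))
        assert files[0] == "arr_unphased_path0001.fasta"
        assert len(files) == 4
        header = (tmp_path / files[0]).read_text().splitlines()[0]
        assert header.startswith(">arr|unphased|path0001|unitigs=A+,")
        assert header.endswith(f"|len={summary.iloc[0]['length']}")


class TestGenomeWidePathCounts:
    def test_two_disjoint_chains(self):
        g = build_graph(
            [(u, None, 10) for u in ("A", "B", "C", "X", "Y")],
            [
                ("A", "+", "B", "+", 0),
                ("B", "+", "C", "+", 0),
                ("X", "+", "Y", "+", 0),
            ],
        )
        table = genome_wide_path_counts(g)
        assert list(table["n_paths"]) == [1, 1]
        assert len(table) == 2

    def test_chain_plus_double_bubble(self, two_bubble_chain):
        g = build_graph(
            [(u.id, None, u.length) for u in two_bubble_chain.unitigs.values()]
            + [("Q", None, 10), ("R", None, 10)],
            [
                (l.from_id, l.from_orient, l.to_id, l.to_orient, 0)
                for l in two_bubble_chain.links
            ]
            + [("Q", "+", "R", "+", 0)],
        )
        table = genome_wide_path_counts(g)
        assert sorted(table["n_paths"]) == [1, 4]

    def test_singleton_component_counts_one(self):
        g = build_graph([("A", None, 10)], [])
        table = genome_wide_path_counts(g)
        assert table.iloc[0].tolist() == [0, "A", "A", 1]

    def test_cap_reports_sentinel(self, two_bubble_chain):
        table = genome_wide_path_counts(two_bubble_chain, max_paths=2)
        assert list(table["n_paths"]) == [">2"]

    def test_random_graphs_match_oracle_counts(self):
        rng = random.Random(424242)
        for _ in range(10):
            graph, links, ids = random_link_graph(rng)
            table = genome_wide_path_counts(graph, max_paths=500_000)
            for row in table.itertuples():
                if row.source == row.sink:
                    continue
                assert row.n_paths == len(
                    oracle_paths(links, row.source, row.sink)
                )
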