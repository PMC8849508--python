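import random

import pytest

from gapspan.graph import (
    ContigGraph,
    GraphEdgePayload,
    GraphError,
    Node,
    build_graph,
    collapse_linear,
    dump_graph,
    find_bubbles,
    load_graph,
    pop_bubbles,
    resolve_repeats_and_branches,
    worked_example_graph,
)
from gapspan.io import SequenceRecord
from tests._oracles import OEdge, brute_resolve, canonical_path


def simple_graph(nodes, edges, lengths=None):
    """nodes: ids; edges: ((a, sa), (b, sb)) or with payload extras."""
    g = ContigGraph()
    lengths = lengths or {}
    for nid in nodes:
        g.add_node(Node(nid, lengths.get(nid, 10_000), [(nid, "+")]))
    for i, spec in enumerate(edges):
        a, b = spec[0], spec[1]
        payload = GraphEdgePayload(
            f"e{i}",
            support=spec[2] if len(spec) > 2 else 1,
            gap_estimate=spec[3] if len(spec) > 3 else 0,
        )
        g.add_edge(a, b, payload)
    return g


def path_set(result):
    return {canonical_path(p.members) for p in result.paths}


class TestBuildGraph:
    def test_no_edges_isolated_nodes(self):
        contigs = [SequenceRecord(f"c{i}", "A" * 100) for i in range(3)]
        g = build_graph(contigs, [])
        assert len(g.nodes) == 3 and not g.edges

    def test_path_graph(self):
        contigs = [SequenceRecord(f"c{i}", "A" * 100) for i in range(1, 4)]
        edges = [
            GraphEdgePayload("x", 2, 100),
        ]

        class E:
            def __init__(self, a, sa, b, sb):
                self.contig_a, self.side_a = a, sa
                self.contig_b, self.side_b = b, sb
                self.edge_id = f"{a}-{b}"
                self.support, self.gap_estimate, self.join_ids = 2, 0, frozenset()

        g = build_graph(contigs, [E("c1", "end", "c2", "begin"), E("c2", "end", "c3", "begin")])
        assert len(g.nodes) == 3 and len(g.edges) == 2

    def test_unknown_contig_error(self):
        contigs = [SequenceRecord("c1", "A" * 100)]

        class E:
            contig_a, side_a, contig_b, side_b = "c1", "end", "nope", "begin"
            edge_id = "bad"
            support, gap_estimate, join_ids = 1, 0, frozenset()

        with pytest.raises(GraphError, match="unknown contig"):
            build_graph(contigs, [E()])

    def test_worked_example_has_12_nodes(self):
        g = worked_example_graph()
        assert len(g.nodes) == 12
        assert len(g.edges) == 13


class TestCollapseLinear:
    def test_path_collapses_to_single_super_node(self):
        g = simple_graph(
            ["c1", "c2", "c3"],
            [(("c1", "end"), ("c2", "begin")), (("c2", "end"), ("c3", "begin"))],
        )
        out = collapse_linear(g)
        assert len(out.nodes) == 1
        (node,) = out.nodes.values()
        assert node.members == [("c1", "+"), ("c2", "+"), ("c3", "+")]

    def test_star_graph_unchanged(self):
        g = simple_graph(
            ["hub", "l1", "l2", "l3"],
            [
                (("hub", "end"), ("l1", "begin")),
                (("hub", "end"), ("l2", "begin")),
                (("hub", "begin"), ("l3", "end")),
            ],
        )
        out = collapse_linear(g)
        assert set(out.nodes) == {"hub", "l1", "l2", "l3"}
        assert len(out.edges) == 3

    def test_collapse_blocked_by_branching_neighbor(self):
        # the two-node stretch next to a fork must not collapse
        g = worked_example_graph()
        out = collapse_linear(g)
        assert "C1" in out.nodes and "C2" in out.nodes
        # but the interior chain B1-B3 does collapse
        supers = [n for n in out.nodes.values() if len(n.members) > 1]
        assert len(supers) == 1
        assert supers[0].members == [("B1", "+"), ("B3", "+")]
        assert supers[0].length == 3000 + 4000 + 200

    def test_orientation_mixed_chain(self):
        # c2 reversed: end-to-end junction then begin-to-begin
        g = simple_graph(
            ["c1", "c2", "c3"],
            [(("c1", "end"), ("c2", "end")), (("c2", "begin"), ("c3", "begin"))],
        )
        out = collapse_linear(g)
        (node,) = out.nodes.values()
        # begin-begin junction flips again: c3 reads forward
        assert node.members == [("c1", "+"), ("c2", "-"), ("c3", "+")]

    def test_idempotent(self):
        g = worked_example_graph()
        once = collapse_linear(g)
        twice = collapse_linear(once)
        assert {tuple(n.members) for n in once.nodes.values()} == {
            tuple(n.members) for n in twice.nodes.values()
        }
        assert len(once.edges) == len(twice.edges)

    def test_isolated_cycle_linearized(self):
        g = simple_graph(
            ["a", "b", "c"],
            [
                (("a", "end"), ("b", "begin")),
                (("b", "end"), ("c", "begin")),
                (("c", "end"), ("a", "begin")),
            ],
        )
        out = collapse_linear(g)
        assert len(out.nodes) == 1
        assert not out.edges
        assert len(out.discarded) == 1


class TestPopBubbles:
    def test_worked_example_bubble(self):
        g = pop_bubbles(worked_example_graph())
        removed = {cid for cid, _ in g.removed_haplotigs}
        assert removed == {"B2"}
        members = {tuple(n.members) for n in g.nodes.values()}
        assert (
            ("C1", "+"), ("C2", "+"), ("B1", "+"), ("B3", "+"), ("C3", "+"), ("C4", "+"),
        ) in members

    def test_equal_length_tie_break_lexicographic(self):
        g = simple_graph(
            ["s", "t", "bA", "bB"],
            [
                (("s", "end"), ("bA", "begin")),
                (("s", "end"), ("bB", "begin")),
                (("bA", "end"), ("t", "begin")),
                (("bB", "end"), ("t", "begin")),
            ],
            lengths={"bA": 5000, "bB": 5000},
        )
        out = pop_bubbles(g)
        assert ("bB", "+") in out.removed_haplotigs
        assert not any(cid == "bA" for cid, _ in out.removed_haplotigs)

    def test_longest_branch_kept(self):
        g = simple_graph(
            ["s", "t", "short", "long"],
            [
                (("s", "end"), ("short", "begin")),
                (("s", "end"), ("long", "begin")),
                (("short", "end"), ("t", "begin")),
                (("long", "end"), ("t", "begin")),
            ],
            lengths={"short": 2000, "long": 9000},
        )
        out = pop_bubbles(g)
        assert ("short", "+") in out.removed_haplotigs

    def test_nested_bubbles_fixed_point(self):
        # outer bubble s->t; one branch contains an inner bubble x->y
        g = simple_graph(
            ["s", "t", "x", "y", "i1", "i2", "alt"],
            [
                (("s", "end"), ("x", "begin")),
                (("x", "end"), ("i1", "begin")),
                (("x", "end"), ("i2", "begin")),
                (("i1", "end"), ("y", "begin")),
                (("i2", "end"), ("y", "begin")),
                (("y", "end"), ("t", "begin")),
                (("s", "end"), ("alt", "begin")),
                (("alt", "end"), ("t", "begin")),
            ],
            lengths={"i1": 8000, "i2": 1000, "alt": 500},
        )
        out = pop_bubbles(g)
        assert find_bubbles(out) == []
        removed = {cid for cid, _ in out.removed_haplotigs}
        assert removed == {"i2", "alt"}
        # everything else collapsed into one linear path
        assert len(out.nodes) == 1

    def test_no_bubble_in_plain_fork(self):
        g = simple_graph(
            ["a", "b", "c"],
            [(("a", "end"), ("b", "begin")), (("a", "end"), ("c", "begin"))],
        )
        assert find_bubbles(g) == []


class TestResolve:
    def test_worked_example_three_paths(self):
        g = pop_bubbles(worked_example_graph())
        result = resolve_repeats_and_branches(g)
        expected = {
            canonical_path(
                [("C1", "+"), ("C2", "+"), ("B1", "+"), ("B3", "+"), ("C3", "+"), ("C4", "+")]
            ),
            canonical_path([("C5", "+"), ("R", "+"), ("C8", "+")]),
            canonical_path([("C6", "+"), ("R", "+"), ("C7", "+")]),
        }
        assert path_set(result) == expected
        assert result.repeat_insertions == {"R": 2}

    def test_worked_example_variant_without_pairing_edge(self):
        g = worked_example_graph()
        (c5c8,) = [
            e for e in g.edges.values()
            if {e.a[0], e.b[0]} == {"C5", "C8"}
        ]
        g.remove_edge(c5c8.id)
        result = resolve_repeats_and_branches(pop_bubbles(g))
        expected = {
            canonical_path(
                [("C1", "+"), ("C2", "+"), ("B1", "+"), ("B3", "+"), ("C3", "+"), ("C4", "+")]
            ),
            canonical_path([("C5", "+")]),
            canonical_path([("C8", "+")]),
            canonical_path([("C6", "+"), ("R", "+"), ("C7", "+")]),
        }
        assert path_set(result) == expected
        assert result.repeat_insertions == {"R": 1}

    def test_one_in_two_out_deletes_outgoing_only(self):
        g = simple_graph(
            ["up", "node", "o1", "o2"],
            [
                (("up", "end"), ("node", "begin"), 3),
                (("node", "end"), ("o1", "begin"), 2),
                (("node", "end"), ("o2", "begin"), 2),
            ],
        )
        result = resolve_repeats_and_branches(g)
        assert path_set(result) == {
            canonical_path([("up", "+"), ("node", "+")]),
            canonical_path([("o1", "+")]),
            canonical_path([("o2", "+")]),
        }

    def test_final_paths_strictly_linear(self):
        result = resolve_repeats_and_branches(pop_bubbles(worked_example_graph()))
        for path in result.paths:
            assert len(path.fills) == len(path.members) - 1
            ids = [cid for cid, _ in path.members]
            non_repeat = [c for c in ids if c not in result.repeat_insertions]
            assert len(non_repeat) == len(set(non_repeat))

    def test_conservation_partition(self):
        g = worked_example_graph()
        input_ids = set(g.nodes)
        result = resolve_repeats_and_branches(pop_bubbles(g))
        in_paths = [cid for p in result.paths for cid in p.contig_ids]
        removed = {cid for cid, _ in result.removed_haplotigs}
        repeats = {cid for cid, n in result.repeat_insertions.items() if n > 0}
        assert set(in_paths) | removed == input_ids
        assert not (set(in_paths) & removed)
        for cid in input_ids - removed - repeats:
            assert in_paths.count(cid) == 1


def random_graph(rng: random.Random):
    n = rng.randint(2, 12)
    nodes = [f"n{i:02d}" for i in range(n)]
    lengths = {nid: rng.randint(1000, 20_000) for nid in nodes}
    n_edges = rng.randint(0, min(18, n * 2))
    used = set()
    edges = []
    for _ in range(n_edges):
        a, b = rng.sample(nodes, 2)
        sa, sb = rng.choice(["begin", "end"]), rng.choice(["begin", "end"])
        key = frozenset([(a, sa), (b, sb)])
        if key in used:
            continue
        used.add(key)
        edges.append(((a, sa), (b, sb), rng.randint(1, 5), rng.randint(-500, 2000)))
    return nodes, lengths, edges


@pytest.mark.parametrize("seed", range(40))
def test_resolve_matches_brute_force(seed):
    """Implementation vs an independent flat-edge-list reference."""
    rng = random.Random(seed)
    for rep in range(6):
        nodes, lengths, edges = random_graph(rng)
        g = simple_graph(nodes, edges, lengths)
        result = resolve_repeats_and_branches(g)
        oracle = brute_resolve(
            nodes,
            [OEdge(a, b, support, gap, f"e{i}") for i, (a, b, support, gap) in enumerate(edges)],
        )
        assert path_set(result) == oracle, (seed, rep, edges)


def test_dump_load_round_trip(tmp_path):
    g = worked_example_graph()
    out = tmp_path / "g.tsv"
    dump_graph(g, out)
    back = load_graph(out)
    assert set(back.nodes) == set(g.nodes)
    assert len(back.edges) == len(g.edges)
    original = {tuple(sorted([e.a, e.b])) for e in g.edges.values()}
    loaded = {tuple(sorted([e.a, e.b])) for e in back.edges.values()}
    assert original == loaded
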