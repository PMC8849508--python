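"""Contig graph construction and resolution to linear scaffold paths.

Nodes are contigs (or super-nodes: collapsed linear chains of contigs)
with a *begin* and an *end* side; edges are side-typed, undirected, and
carry the bundled-junction payload. Resolution proceeds by collapsing
linear chains, iteratively popping bubbles (keeping the longest branch),
temporarily removing repeat nodes (>=2 edges on each side), deleting all
edges on any remaining side with >=2 edges, and finally re-inserting
repeats into the resulting linear paths, duplicating their sequence per
insertion.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

log = logging.getLogger(__name__)

Side = str  # 'begin' | 'end'


def opposite(side: Side) -> Side:
    return "end" if side == "begin" else "begin"


class EdgePayload(Protocol):
    edge_id: str
    gap_estimate: int

    @property
    def support(self) -> int: ...

    @property
    def join_ids(self) -> frozenset[str]: ...


@dataclass(frozen=True)
class GraphEdgePayload:
    """Minimal payload used for hand-built graphs and debug dumps."""

    edge_id: str
    support: int = 1
    gap_estimate: int = 0
    join_ids: frozenset[str] = frozenset()


@dataclass
class Node:
    id: str
    length: int
    # ordered oriented contig list; singleton for plain contig nodes
    members: list[tuple[str, str]]
    # payload per junction between consecutive members (len == members-1)
    member_gaps: list[object] = field(default_factory=list)


@dataclass
class Edge:
    id: int
    a: tuple[str, Side]  # (node id, side)
    b: tuple[str, Side]
    payload: object

    def other(self, end: tuple[str, Side]) -> tuple[str, Side]:
        return self.b if end == self.a else self.a


class GraphError(ValueError):
    pass


class ContigGraph:
    """Side-typed undirected multigraph over contigs/super-nodes."""

    def __init__(self) -> None:
        self.nodes: dict[str, Node] = {}
        self.edges: dict[int, Edge] = {}
        self._next_edge = 0
        self._next_super = 0
        self.removed_haplotigs: list[tuple[str, str]] = []  # (cid, orient)
        self.discarded: list[object] = []  # payloads of dropped junctions

    # -- construction -----------------------------------------------------
    def add_node(self, node: Node) -> None:
        if node.id in self.nodes:
            raise GraphError(f"duplicate node {node.id!r}")
        self.nodes[node.id] = node

    def add_edge(self, a: tuple[str, Side], b: tuple[str, Side], payload: object) -> int:
        for nid, side in (a, b):
            if nid not in self.nodes:
                raise GraphError(f"edge endpoint names unknown node {nid!r}")
            if side not in ("begin", "end"):
                raise GraphError(f"bad side {side!r}")
        if a == b:
            raise GraphError(f"self-loop on a single side at {a}")
        eid = self._next_edge
        self._next_edge += 1
        self.edges[eid] = Edge(eid, a, b, payload)
        return eid

    def copy(self) -> "ContigGraph":
        g = ContigGraph()
        g.nodes = {
            nid: Node(n.id, n.length, list(n.members), list(n.member_gaps))
            for nid, n in self.nodes.items()
        }
        g.edges = {eid: Edge(e.id, e.a, e.b, e.payload) for eid, e in self.edges.items()}
        g._next_edge = self._next_edge
        g._next_super = self._next_super
        g.removed_haplotigs = list(self.removed_haplotigs)
        g.discarded = list(self.discarded)
        return g

    # -- queries ----------------------------------------------------------
    def edges_at(self, nid: str, side: Side) -> list[Edge]:
        end = (nid, side)
        return sorted(
            (e for e in self.edges.values() if e.a == end or e.b == end),
            key=lambda e: e.id,
        )

    def degree(self, nid: str, side: Side) -> int:
        return len(self.edges_at(nid, side))

    def node_edges(self, nid: str) -> list[Edge]:
        return sorted(
            (e for e in self.edges.values() if e.a[0] == nid or e.b[0] == nid),
            key=lambda e: e.id,
        )

    def contact(self, nid: str, side: Side) -> tuple[str, Side]:
        """The member contig (id, side) exposed at a node side."""
        node = self.nodes[nid]
        if side == "begin":
            cid, orient = node.members[0]
            return (cid, "begin" if orient == "+" else "end")
        cid, orient = node.members[-1]
        return (cid, "end" if orient == "+" else "begin")

    # -- mutation ---------------------------------------------------------
    def remove_edge(self, eid: int, discard: bool = False) -> Edge:
        e = self.edges.pop(eid)
        if discard:
            self.discarded.append(e.payload)
        return e

    def remove_node(self, nid: str) -> tuple[Node, list[Edge]]:
        incident = self.node_edges(nid)
        for e in incident:
            self.edges.pop(e.id)
        return self.nodes.pop(nid), incident


def build_graph(contigs: Iterable, edges: Iterable) -> ContigGraph:
    """One node per contig, one side-typed edge per bundled junction.

    ``contigs`` supply ``id``/``length``; ``edges`` supply
    ``contig_a``/``side_a``/``contig_b``/``side_b`` plus payload fields.
    Self-junctions (both ends on the same contig) carry no scaffolding
    information at this granularity and are discarded with a note.
    """
    g = ContigGraph()
    for c in contigs:
        g.add_node(Node(c.id, c.length, [(c.id, "+")]))
    for e in edges:
        if e.contig_a not in g.nodes or e.contig_b not in g.nodes:
            missing = e.contig_a if e.contig_a not in g.nodes else e.contig_b
            raise GraphError(f"edge {e.edge_id} names unknown contig {missing!r}")
        if e.contig_a == e.contig_b:
            log.info("dropping self-junction %s (circular evidence)", e.edge_id)
            g.discarded.append(e)
            continue
        g.add_edge((e.contig_a, e.side_a), (e.contig_b, e.side_b), e)
    return g


# ---------------------------------------------------------------------------
# Linear-chain collapsing
# ---------------------------------------------------------------------------


def _is_chain_node(g: ContigGraph, nid: str) -> bool:
    return g.degree(nid, "begin") <= 1 and g.degree(nid, "end") <= 1


def _edge_sort_key(e: Edge) -> tuple:
    return tuple(sorted([e.a, e.b])) + (e.id,)


def collapse_linear(graph: ContigGraph) -> ContigGraph:
    """Collapse maximal chains of nodes having <=1 edge per side.

    Idempotent. An isolated cycle of chain nodes is linearized by
    discarding its smallest-keyed junction.
    """
    g = graph.copy()
    chain = {nid for nid in g.nodes if _is_chain_node(g, nid)}
    contractible = {
        e.id
        for e in g.edges.values()
        if e.a[0] != e.b[0] and e.a[0] in chain and e.b[0] in chain
    }
    if not contractible:
        return g

    # connected components over contractible edges
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for eid in contractible:
        e = g.edges[eid]
        union(e.a[0], e.b[0])
    comps: dict[str, list[str]] = {}
    for nid in chain:
        comps.setdefault(find(nid), []).append(nid)

    for root in sorted(comps, key=lambda r: min(comps[r])):
        members = sorted(comps[root])
        if len(members) < 2:
            continue
        comp_edges = [
            g.edges[eid]
            for eid in sorted(contractible)
            if eid in g.edges and g.edges[eid].a[0] in comps[root]
        ]
        incidence: dict[str, list[Edge]] = {nid: [] for nid in members}
        for e in comp_edges:
            incidence[e.a[0]].append(e)
            incidence[e.b[0]].append(e)
        terminals = sorted(nid for nid in members if len(incidence[nid]) == 1)
        if not terminals:  # cycle: linearize deterministically
            # tie-break on member-contig contacts so the choice does not
            # depend on synthetic super-node naming
            drop = min(
                comp_edges,
                key=lambda e: tuple(sorted([g.contact(*e.a), g.contact(*e.b)])),
            )
            g.remove_edge(drop.id, discard=True)
            comp_edges = [e for e in comp_edges if e.id != drop.id]
            incidence = {nid: [] for nid in members}
            for e in comp_edges:
                incidence[e.a[0]].append(e)
                incidence[e.b[0]].append(e)
            terminals = sorted(nid for nid in members if len(incidence[nid]) == 1)
        start = terminals[0]

        # walk the chain from `start`
        ordered: list[tuple[Node, str]] = []  # (node, orientation)
        gaps: list[object] = []
        prev_edge: Edge | None = None
        cur = start
        while True:
            node = g.nodes[cur]
            if prev_edge is None:
                out_edges = incidence[cur]
                exit_side = (
                    out_edges[0].a[1] if out_edges[0].a[0] == cur else out_edges[0].b[1]
                )
                orient = "+" if exit_side == "end" else "-"
            else:
                enter_side = prev_edge.a[1] if prev_edge.a[0] == cur else prev_edge.b[1]
                orient = "+" if enter_side == "begin" else "-"
            ordered.append((node, orient))
            nxt = [e for e in incidence[cur] if e is not prev_edge]
            if not nxt:
                break
            prev_edge = nxt[0]
            gaps.append(prev_edge.payload)
            cur = prev_edge.a[0] if prev_edge.b[0] == cur else prev_edge.b[0]

        new_members: list[tuple[str, str]] = []
        new_gaps: list[object] = []
        for i, (node, orient) in enumerate(ordered):
            if i > 0:
                new_gaps.append(gaps[i - 1])
            if orient == "+":
                new_members.extend(node.members)
                new_gaps.extend(node.member_gaps)
            else:
                new_members.extend(
                    (cid, "-" if o == "+" else "+") for cid, o in reversed(node.members)
                )
                new_gaps.extend(reversed(node.member_gaps))

        length = sum(node.length for node, _ in ordered) + sum(
            getattr(p, "gap_estimate", 0) for p in gaps
        )
        g._next_super += 1
        new_id = f"__chain{g._next_super}"
        new_node = Node(new_id, length, new_members, new_gaps)

        # outer edges attach at the free sides of the two walk ends
        first_node, first_orient = ordered[0]
        last_node, last_orient = ordered[-1]
        free_first = (first_node.id, "begin" if first_orient == "+" else "end")
        free_last = (last_node.id, "end" if last_orient == "+" else "begin")
        remap = {free_first: (new_id, "begin"), free_last: (new_id, "end")}

        member_ids = {node.id for node, _ in ordered}
        for e in list(g.edges.values()):
            if e.id in contractible and e.a[0] in member_ids:
                g.remove_edge(e.id)
                continue
            if e.a in remap:
                e.a = remap[e.a]
            if e.b in remap:
                e.b = remap[e.b]
        for node, _ in ordered:
            if node.id in g.nodes:
                del g.nodes[node.id]
        g.add_node(new_node)
    return g


# ---------------------------------------------------------------------------
# Bubble popping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bubble:
    source: tuple[str, Side]
    sink: tuple[str, Side]
    branches: tuple[str, ...]  # node ids of the parallel branches


def find_bubbles(g: ContigGraph) -> list[Bubble]:
    """Parallel single-node branches sharing one source and one sink."""
    bubbles = []
    seen: set[tuple] = set()
    for x in sorted(g.nodes):
        for sx in ("begin", "end"):
            groups: dict[tuple[str, Side], list[str]] = {}
            for e in g.edges_at(x, sx):
                b_nid, b_side = e.other((x, sx))
                if b_nid == x or not _is_chain_node(g, b_nid):
                    continue
                far = g.edges_at(b_nid, opposite(b_side))
                if len(far) != 1:
                    continue
                y = far[0].other((b_nid, opposite(b_side)))
                if y[0] in (x, b_nid):
                    continue
                groups.setdefault(y, []).append(b_nid)
            for y, branch_nodes in sorted(groups.items()):
                if len(branch_nodes) < 2:
                    continue
                key = tuple(sorted([(x, sx), y]))
                if key in seen:
                    continue
                seen.add(key)
                bubbles.append(Bubble((x, sx), y, tuple(sorted(set(branch_nodes)))))
    return bubbles


def _branch_rank(g: ContigGraph, nid: str) -> tuple:
    node = g.nodes[nid]
    return (-node.length, min(cid for cid, _ in node.members))


def pop_bubbles(graph: ContigGraph) -> ContigGraph:
    """Iteratively keep only the longest branch of every bubble.

    Re-collapses after every pop; terminates at a bubble-free fixed
    point. Dropped branch contigs are appended to
    ``graph.removed_haplotigs``.
    """
    g = collapse_linear(graph)
    while True:
        bubbles = find_bubbles(g)
        if not bubbles:
            return g
        bub = bubbles[0]
        keep = min(bub.branches, key=lambda nid: _branch_rank(g, nid))
        for nid in bub.branches:
            if nid == keep:
                continue
            node, edges = g.remove_node(nid)
            g.removed_haplotigs.extend(node.members)
            g.discarded.extend(e.payload for e in edges)
        g = collapse_linear(g)


# ---------------------------------------------------------------------------
# Repeat removal, branch breaking, path extraction, repeat re-insertion
# ---------------------------------------------------------------------------


@dataclass
class RepeatEdge:
    rep_side: Side
    far: tuple[str, Side]  # contact contig (id, side) on the far node
    payload: object


@dataclass
class RepeatRecord:
    cid: str
    length: int
    edges: list[RepeatEdge]


@dataclass
class ScaffoldPath:
    """Ordered oriented contigs with one junction payload per gap."""

    members: list[tuple[str, str]]
    fills: list[object]  # len == members - 1

    def canonical(self) -> tuple:
        fwd = tuple(self.members)
        rev = tuple((cid, "-" if o == "+" else "+") for cid, o in reversed(self.members))
        return min(fwd, rev)

    @property
    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.members]


@dataclass
class ResolveResult:
    paths: list[ScaffoldPath]
    repeat_insertions: dict[str, int]  # repeat contig id -> times inserted
    removed_haplotigs: list[tuple[str, str]]
    discarded: list[object]


def _facing_sides(left: tuple[str, str], right: tuple[str, str]) -> tuple:
    (lc, lo), (rc, ro) = left, right
    return (lc, "end" if lo == "+" else "begin"), (rc, "begin" if ro == "+" else "end")


def resolve_repeats_and_branches(graph: ContigGraph) -> ResolveResult:
    """Resolve a (bubble-free) graph into linear scaffold paths.

    Steps: mark nodes with >=2 edges on both sides as repeats and remove
    them; re-collapse; delete every edge on any side that still has >=2
    edges (one global scan over a frozen degree snapshot); extract the
    remaining simple paths; re-insert each repeat wherever path evidence
    supports a flank pairing, duplicating its sequence per insertion.
    """
    g = collapse_linear(graph)

    repeats: list[RepeatRecord] = []
    for nid in sorted(g.nodes):
        if g.degree(nid, "begin") >= 2 and g.degree(nid, "end") >= 2:
            node = g.nodes[nid]
            if len(node.members) != 1:
                # cannot happen: super-nodes inherit <=1 edge per side
                raise GraphError(f"super-node {nid} classified as repeat")
            cid = node.members[0][0]
            rec = RepeatRecord(cid, node.length, [])
            for e in g.node_edges(nid):
                my = e.a if e.a[0] == nid else e.b
                far_nid, far_side = e.other(my)
                if far_nid == nid:
                    continue
                rec.edges.append(
                    RepeatEdge(my[1], g.contact(far_nid, far_side), e.payload)
                )
            repeats.append(rec)
    for rec in repeats:
        g.remove_node(rec.cid)

    g = collapse_linear(g)

    # branch breaking over a frozen snapshot
    to_delete: set[int] = set()
    for nid in sorted(g.nodes):
        for side in ("begin", "end"):
            edges = g.edges_at(nid, side)
            if len(edges) >= 2:
                to_delete.update(e.id for e in edges)
    for eid in sorted(to_delete):
        g.remove_edge(eid, discard=True)

    g = collapse_linear(g)
    if g.edges:
        raise GraphError("graph not fully linearized after branch breaking")

    raw_paths: dict[int, tuple[list, list]] = {}
    for idx, nid in enumerate(
        sorted(g.nodes, key=lambda n: min(cid for cid, _ in g.nodes[n].members))
    ):
        node = g.nodes[nid]
        raw_paths[idx] = (list(node.members), list(node.member_gaps))

    repeat_insertions: dict[str, int] = {rec.cid: 0 for rec in repeats}
    repeats_by_cid = {rec.cid: rec for rec in repeats}

    # (a) insert repeats into surviving through-junctions
    for members, fills in raw_paths.values():
        j = 0
        while j < len(fills):
            fl, fr = _facing_sides(members[j], members[j + 1])
            best = None
            for rec in sorted(repeats, key=lambda r: r.cid):
                for e1 in rec.edges:
                    if e1.far != fl:
                        continue
                    for e2 in rec.edges:
                        if e2 is e1 or e2.rep_side != opposite(e1.rep_side):
                            continue
                        if e2.far != fr:
                            continue
                        score = e1.payload.support + e2.payload.support
                        cand = (-score, rec.cid, e1.rep_side, e1, e2, rec)
                        if best is None or cand[:3] < best[:3]:
                            best = cand
            if best is not None:
                _, cid, s1, e1, e2, rec = best
                orient = "+" if s1 == "begin" else "-"
                through = fills[j]
                members.insert(j + 1, (cid, orient))
                fills[j : j + 1] = [e1.payload, e2.payload]
                repeat_insertions[cid] += 1
                j += 2
            else:
                j += 1

    # (b) pair free path ends through a repeat when reads traverse it
    contact_of_end: dict[tuple[str, Side], tuple[int, str]] = {}

    def register_ends(idx: int) -> None:
        members, _ = raw_paths[idx]
        (c0, o0), (ck, ok) = members[0], members[-1]
        contact_of_end[(c0, "begin" if o0 == "+" else "end")] = (idx, "L")
        contact_of_end[(ck, "end" if ok == "+" else "begin")] = (idx, "R")

    for idx in raw_paths:
        register_ends(idx)

    candidates = []
    for rec in sorted(repeats, key=lambda r: r.cid):
        for e1 in rec.edges:
            if e1.rep_side != "begin":
                continue
            for e2 in rec.edges:
                if e2.rep_side != "end":
                    continue
                shared = frozenset(getattr(e1.payload, "join_ids", ())) & frozenset(
                    getattr(e2.payload, "join_ids", ())
                )
                if not shared:
                    continue
                score = e1.payload.support + e2.payload.support
                candidates.append((-score, rec.cid, e1.far, e2.far, e1, e2))
    for _, cid, far1, far2, e1, e2 in sorted(candidates, key=lambda c: c[:4]):
        end1 = contact_of_end.get(far1)
        end2 = contact_of_end.get(far2)
        if end1 is None or end2 is None or end1[0] == end2[0]:
            continue
        (i1, w1), (i2, w2) = end1, end2
        m1, f1 = raw_paths[i1]
        m2, f2 = raw_paths[i2]
        if w1 == "L":  # flip path 1 so its paired end is on the right
            m1 = [(c, "-" if o == "+" else "+") for c, o in reversed(m1)]
            f1 = list(reversed(f1))
        if w2 == "R":  # flip path 2 so its paired end is on the left
            m2 = [(c, "-" if o == "+" else "+") for c, o in reversed(m2)]
            f2 = list(reversed(f2))
        merged_members = m1 + [(cid, "+")] + m2
        merged_fills = f1 + [e1.payload] + [e2.payload] + f2
        for contact, end in list(contact_of_end.items()):
            if end[0] in (i1, i2):
                del contact_of_end[contact]
        raw_paths[i1] = (merged_members, merged_fills)
        del raw_paths[i2]
        register_ends(i1)
        repeat_insertions[cid] += 1

    # (c) leftover repeats stand alone
    for rec in sorted(repeats, key=lambda r: r.cid):
        if repeat_insertions[rec.cid] == 0:
            idx = max(raw_paths, default=-1) + 1
            raw_paths[idx] = ([(rec.cid, "+")], [])
            repeat_insertions[rec.cid] = 1

    paths = [
        ScaffoldPath(members, fills)
        for members, fills in sorted(
            raw_paths.values(), key=lambda mf: min(cid for cid, _ in mf[0])
        )
    ]
    return ResolveResult(
        paths=paths,
        repeat_insertions=repeat_insertions,
        removed_haplotigs=list(g.removed_haplotigs),
        discarded=list(g.discarded),
    )


# ---------------------------------------------------------------------------
# Debug dump / load (also the worked-example fixture format)
# ---------------------------------------------------------------------------


def dump_graph(g: ContigGraph, path: str | Path) -> None:
    with open(path, "w") as out:
        for nid in sorted(g.nodes):
            out.write(f"#node\t{nid}\t{g.nodes[nid].length}\n")
        for e in sorted(g.edges.values(), key=_edge_sort_key):
            payload = e.payload
            out.write(
                f"{e.a[0]}\t{e.a[1]}\t{e.b[0]}\t{e.b[1]}\t"
                f"{getattr(payload, 'support', 1)}\t"
                f"{getattr(payload, 'gap_estimate', 0)}\n"
            )


def load_graph(path: str | Path) -> ContigGraph:
    """Load a graph from the tab-separated debug/edge-list format."""
    g = ContigGraph()
    edge_rows = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#node"):
                _, nid, length = line.split("\t")
                g.add_node(Node(nid, int(length), [(nid, "+")]))
            elif line.startswith("#"):
                continue
            else:
                edge_rows.append(line.split("\t"))
    for i, row in enumerate(edge_rows):
        a, sa, b, sb = row[:4]
        support = int(row[4]) if len(row) > 4 else 1
        gap = int(row[5]) if len(row) > 5 else 0
        payload = GraphEdgePayload(f"fixture_edge_{i}", support, gap)
        g.add_edge((a, sa), (b, sb), payload)
    return g


def worked_example_graph() -> ContigGraph:
    """The shipped 12-node demonstration graph (bubble + repeat)."""
    from importlib.resources import files

    return load_graph(str(files("gapspan.data") / "worked_example_graph.tsv"))
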