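"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's graph machinery: the graph
resolver works directly on a flat edge list at contig granularity and
re-derives paths by naive component walking.
"""
from __future__ import annotations

from dataclasses import dataclass


# ---------------------------------------------------------------------------
# Best-alignment selection oracle (recursive dominance definition)
# ---------------------------------------------------------------------------


def brute_select_best(alignments):
    """An alignment is kept unless some kept, higher-ranked alignment of
    the same query overlaps >=50% of its query interval."""

    def rank(a):
        return (-a.matches, -a.block_len, a.target_id, a.target_start, a.query_start)

    def overlap(a, b):
        return max(0, min(a.query_end, b.query_end) - max(a.query_start, b.query_start))

    kept = []
    queries = sorted({a.query_id for a in alignments})
    for qid in queries:
        group = sorted((a for a in alignments if a.query_id == qid), key=rank)
        status: dict[int, bool] = {}

        def is_kept(i):
            if i in status:
                return status[i]
            a = group[i]
            ok = True
            for j in range(i):
                if not is_kept(j):
                    continue
                if overlap(a, group[j]) >= 0.5 * (a.query_end - a.query_start):
                    ok = False
                    break
            status[i] = ok
            return ok

        winners = [group[i] for i in range(len(group)) if is_kept(i)]
        kept.extend(sorted(winners, key=lambda a: (a.query_start, a.query_end, a.target_id)))
    return kept


# ---------------------------------------------------------------------------
# Graph-resolution oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OEdge:
    a: tuple[str, str]  # (contig, side)
    b: tuple[str, str]
    support: int = 1
    gap: int = 0
    eid: str = ""

    def other(self, end):
        return self.b if end == self.a else self.a


def _flip(orient):
    return "-" if orient == "+" else "+"


def _opp(side):
    return "end" if side == "begin" else "begin"


def canonical_path(members):
    fwd = tuple(members)
    rev = tuple((c, _flip(o)) for c, o in reversed(members))
    return min(fwd, rev)


def brute_resolve(node_ids, edges):
    """Reference for resolve_repeats_and_branches at contig granularity.

    Returns a frozenset of canonical member tuples.
    """
    edges = list(edges)

    def degree(edge_list, end):
        return sum(1 for e in edge_list if e.a == end or e.b == end)

    # 1. repeats: >=2 edges on both sides; record their edges, remove them
    repeats = []
    for nid in sorted(node_ids):
        if degree(edges, (nid, "begin")) >= 2 and degree(edges, (nid, "end")) >= 2:
            repeats.append(nid)
    repeat_edges = {
        nid: [e for e in edges if e.a[0] == nid or e.b[0] == nid] for nid in repeats
    }
    edges = [e for e in edges if e.a[0] not in repeats and e.b[0] not in repeats]
    live = [nid for nid in node_ids if nid not in repeats]

    # 2. branch breaking: delete ALL edges on any side with >=2 edges
    bad_sides = {
        (nid, side)
        for nid in live
        for side in ("begin", "end")
        if degree(edges, (nid, side)) >= 2
    }
    edges = [e for e in edges if e.a not in bad_sides and e.b not in bad_sides]

    # 3. cycles: every side now has <=1 edge; drop the smallest-keyed edge
    #    of any component with no free end
    def components():
        seen, comps = set(), []
        adj = {}
        for e in edges:
            adj.setdefault(e.a[0], []).append(e)
            adj.setdefault(e.b[0], []).append(e)
        for nid in sorted(live):
            if nid in seen:
                continue
            stack, comp = [nid], set()
            while stack:
                cur = stack.pop()
                if cur in comp:
                    continue
                comp.add(cur)
                for e in adj.get(cur, []):
                    stack.append(e.a[0])
                    stack.append(e.b[0])
            seen |= comp
            comps.append(sorted(comp))
        return comps

    while True:
        dropped = False
        for comp in components():
            comp_edges = [e for e in edges if e.a[0] in comp]
            free_end = any(
                degree(comp_edges, (nid, side)) == 0
                for nid in comp
                for side in ("begin", "end")
            )
            if comp_edges and not free_end:
                victim = min(comp_edges, key=lambda e: tuple(sorted([e.a, e.b])))
                edges.remove(victim)
                dropped = True
        if not dropped:
            break

    # 4. walk each component into an ordered oriented path
    paths = []
    placed = set()
    for comp in components():
        comp_edges = [e for e in edges if e.a[0] in comp]
        if not comp_edges:
            for nid in comp:
                paths.append([(nid, "+")])
                placed.add(nid)
            continue
        ends = [
            (nid, side)
            for nid in comp
            for side in ("begin", "end")
            if degree(comp_edges, (nid, side)) == 0
        ]
        start = min(ends)
        members = []
        cur_node, free_side = start
        prev_edge = None
        while True:
            orient = "+" if free_side == "begin" else "-"
            members.append((cur_node, orient))
            placed.add(cur_node)
            exit_end = (cur_node, _opp(free_side))
            nxt = [e for e in comp_edges if (e.a == exit_end or e.b == exit_end) and e is not prev_edge]
            if not nxt:
                break
            prev_edge = nxt[0]
            cur_node, enter_side = prev_edge.other(exit_end)
            free_side = enter_side
        paths.append(members)

    # 5. re-insert repeats at junctions whose flanking contacts match
    def facing(left, right):
        (lc, lo), (rc, ro) = left, right
        return (lc, "end" if lo == "+" else "begin"), (rc, "begin" if ro == "+" else "end")

    inserted = {nid: 0 for nid in repeats}
    for members in paths:
        j = 0
        while j < len(members) - 1:
            fl, fr = facing(members[j], members[j + 1])
            best = None
            for nid in sorted(repeats):
                for e1 in repeat_edges[nid]:
                    my1 = e1.a if e1.a[0] == nid else e1.b
                    if e1.other(my1) != fl:
                        continue
                    for e2 in repeat_edges[nid]:
                        my2 = e2.a if e2.a[0] == nid else e2.b
                        if e2 is e1 or my2[1] != _opp(my1[1]):
                            continue
                        if e2.other(my2) != fr:
                            continue
                        cand = (-(e1.support + e2.support), nid, my1[1])
                        if best is None or cand < best:
                            best = cand
            if best is not None:
                _, nid, s1 = best
                members.insert(j + 1, (nid, "+" if s1 == "begin" else "-"))
                inserted[nid] += 1
                j += 2
            else:
                j += 1
    for nid in sorted(repeats):
        if inserted[nid] == 0:
            paths.append([(nid, "+")])

    return frozenset(canonical_path(m) for m in paths)
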