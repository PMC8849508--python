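"""Aligner invocation, best-alignment selection, proper-alignment
classification and link extraction between contig ends.

A "proper" alignment is a long alignment of a joining sequence to a
contig whose unaligned read extension past a contig end leaves no more
than ``max_overhang`` bp of the contig unaligned. Joining sequences
properly aligned to two or more contigs create links between the facing
contig ends; concordant links are bundled into weighted edges.
"""
from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median_low
from typing import Iterable, Literal

from .io import AlignmentRecord

DEFAULT_MIN_ALN_LEN = 5000
DEFAULT_MAX_OVERHANG = 1000
DEFAULT_ANCHOR_BP = 200

Mode = Literal["ont", "pbclr", "asm"]
Side = Literal["begin", "end"]

MODE_PRESETS: dict[str, str] = {"ont": "map-ont", "pbclr": "map-pb", "asm": "asm20"}


def default_min_support(mode: str) -> int:
    """Read modes demand >1 concordant link per junction; asm mode 1."""
    return 1 if mode == "asm" else 2


class ConfigurationError(RuntimeError):
    pass


class AlignerError(RuntimeError):
    pass


def run_aligner(
    contigs: str | Path,
    joins: str | Path,
    mode: Mode,
    threads: int = 1,
    out_paf: str | Path | None = None,
) -> Path:
    """Map joining sequences to contigs with minimap2, returning a PAF path."""
    if mode not in MODE_PRESETS:
        raise ConfigurationError(f"unknown mode {mode!r}; expected ont/pbclr/asm")
    if shutil.which("minimap2") is None:
        raise ConfigurationError(
            "minimap2 not found on PATH; install minimap2 or supply a "
            "precomputed PAF with --paf"
        )
    out = Path(out_paf) if out_paf else Path(str(joins) + ".paf")
    cmd = [
        "minimap2",
        "-x", MODE_PRESETS[mode],
        "-t", str(threads),
        "-o", str(out),
        str(contigs),
        str(joins),
    ]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise AlignerError(f"minimap2 failed ({proc.returncode}): {proc.stderr[-2000:]}")
    return out


def _qoverlap(a: AlignmentRecord, b: AlignmentRecord) -> int:
    return max(0, min(a.query_end, b.query_end) - max(a.query_start, b.query_start))


def select_best(alignments: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep the dominant alignment per query interval.

    Alignments of each query are ranked by (matches, block_len, target
    id); an alignment whose query interval overlaps a kept
    higher-ranked alignment by >=50% of its own length is dropped.
    Output is ordered by (query id, query start).
    """
    by_query: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        by_query.setdefault(a.query_id, []).append(a)
    out: list[AlignmentRecord] = []
    for qid in sorted(by_query):
        ranked = sorted(
            by_query[qid],
            key=lambda a: (-a.matches, -a.block_len, a.target_id, a.target_start, a.query_start),
        )
        kept: list[AlignmentRecord] = []
        for a in ranked:
            span = a.query_end - a.query_start
            if all(_qoverlap(a, k) < 0.5 * span for k in kept):
                kept.append(a)
        out.extend(sorted(kept, key=lambda a: (a.query_start, a.query_end, a.target_id)))
    return out


@dataclass(frozen=True)
class ProperAlignment:
    """An accepted long, end-proximal alignment."""

    aln: AlignmentRecord
    contig_end_touched: str  # 'begin' | 'end' | 'both'
    overhang_bp: int


@dataclass(frozen=True)
class Rejection:
    aln: AlignmentRecord
    reason: str  # 'too_short' | 'overhang_exceeded' | 'internal'


def classify_proper(
    aln: AlignmentRecord,
    min_aln_len: int = DEFAULT_MIN_ALN_LEN,
    max_overhang: int = DEFAULT_MAX_OVERHANG,
) -> ProperAlignment | Rejection:
    """Accept iff the block is long enough and every contig end the read
    extends past is within ``max_overhang`` of the alignment boundary.

    A contig side counts as "touched" only when the unaligned read
    extension on that side reaches at least to the contig end (extension
    >= unaligned contig remainder); if the read terminates strictly
    first, that side imposes no constraint.
    """
    if aln.block_len < min_aln_len:
        return Rejection(aln, "too_short")
    # unaligned read extension mapped onto contig-forward sides
    if aln.strand == "+":
        ext_begin = aln.query_start
        ext_end = aln.query_len - aln.query_end
    else:
        ext_begin = aln.query_len - aln.query_end
        ext_end = aln.query_start
    dist_begin = aln.target_start
    dist_end = aln.target_len - aln.target_end
    touched = []
    overhang = 0
    if ext_begin >= dist_begin:
        touched.append("begin")
        overhang = max(overhang, dist_begin)
    if ext_end >= dist_end:
        touched.append("end")
        overhang = max(overhang, dist_end)
    if not touched:
        return Rejection(aln, "internal")
    if overhang > max_overhang:
        return Rejection(aln, "overhang_exceeded")
    return ProperAlignment(aln, "both" if len(touched) == 2 else touched[0], overhang)


def filter_proper(
    alignments: Iterable[AlignmentRecord],
    min_aln_len: int = DEFAULT_MIN_ALN_LEN,
    max_overhang: int = DEFAULT_MAX_OVERHANG,
) -> tuple[list[ProperAlignment], list[Rejection]]:
    accepted, rejected = [], []
    for a in alignments:
        res = classify_proper(a, min_aln_len, max_overhang)
        (accepted if isinstance(res, ProperAlignment) else rejected).append(res)
    return accepted, rejected


@dataclass(frozen=True)
class Link:
    """One oriented junction between two contig ends, from one join.

    Endpoints are stored in canonical order ((id, side) sorted); when
    the read traversed the junction in the opposite direction,
    ``flipped`` is set and the read interval must be reverse
    complemented before use.
    """

    join_id: str
    contig_a: str
    side_a: Side
    contig_b: str
    side_b: Side
    gap_estimate: int
    read_start: int
    read_end: int
    flipped: bool

    @property
    def key(self) -> tuple[str, Side, str, Side]:
        return (self.contig_a, self.side_a, self.contig_b, self.side_b)

    @property
    def relative_orientation(self) -> str:
        return "forward" if self.side_a != self.side_b else "reverse"


def _facing_side(aln: AlignmentRecord, left_of_junction: bool) -> Side:
    """Which contig end faces the junction for an alignment that sits to
    the left (earlier on the read) or right of it."""
    if left_of_junction:
        return "end" if aln.strand == "+" else "begin"
    return "begin" if aln.strand == "+" else "end"


def _end_projection(aln: AlignmentRecord, side: Side) -> int:
    """Read coordinate where the given contig end projects, extrapolating
    past the alignment boundary."""
    if side == "end":
        tail = aln.target_len - aln.target_end
        return aln.query_end + tail if aln.strand == "+" else aln.query_start - tail
    head = aln.target_start
    return aln.query_start - head if aln.strand == "+" else aln.query_end + head


def extract_links(
    proper: Iterable[ProperAlignment],
    anchor_bp: int = DEFAULT_ANCHOR_BP,
    max_overhang: int = DEFAULT_MAX_OVERHANG,
) -> list[Link]:
    """Turn each join's ordered proper alignments into junction links.

    Joins aligned to fewer than two distinct contigs contribute nothing.
    Links are made between alignments adjacent along the read only. The
    gap estimate is the read-space distance between the projections of
    the two facing contig ends (negative when they overlap); junctions
    overlapping by more than 2x ``max_overhang`` are discarded.
    """
    by_join: dict[str, list[ProperAlignment]] = {}
    for p in proper:
        by_join.setdefault(p.aln.query_id, []).append(p)
    links: list[Link] = []
    for join_id in sorted(by_join):
        group = sorted(
            by_join[join_id],
            key=lambda p: (p.aln.query_start, p.aln.query_end, p.aln.target_id),
        )
        if len({p.aln.target_id for p in group}) < 2:
            continue
        for left, right in zip(group, group[1:]):
            la, ra = left.aln, right.aln
            side_l = _facing_side(la, left_of_junction=True)
            side_r = _facing_side(ra, left_of_junction=False)
            if la.target_id == ra.target_id and side_l == side_r:
                continue  # same contig, same side: not a usable junction
            # the junction-facing end must be reachable by the read
            if left.contig_end_touched not in (side_l, "both"):
                continue
            if right.contig_end_touched not in (side_r, "both"):
                continue
            q_left = _end_projection(la, side_l)
            q_right = _end_projection(ra, side_r)
            gap = q_right - q_left
            if gap < -2 * max_overhang:
                continue
            lo = max(0, min(q_left, q_right) - anchor_bp)
            hi = min(la.query_len, max(q_left, q_right) + anchor_bp)
            if hi <= lo:
                continue
            a, b = (la.target_id, side_l), (ra.target_id, side_r)
            flipped = (b, a) < (a, b)
            if flipped:
                a, b = b, a
            links.append(
                Link(
                    join_id=join_id,
                    contig_a=a[0], side_a=a[1],
                    contig_b=b[0], side_b=b[1],
                    gap_estimate=gap,
                    read_start=lo,
                    read_end=hi,
                    flipped=flipped,
                )
            )
    return links


@dataclass
class BundledEdge:
    """All concordant links between one pair of contig ends."""

    edge_id: str
    contig_a: str
    side_a: Side
    contig_b: str
    side_b: Side
    gap_estimate: int
    links: list[Link] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.links)

    @property
    def join_ids(self) -> frozenset[str]:
        return frozenset(l.join_id for l in self.links)

    @property
    def key(self) -> tuple[str, Side, str, Side]:
        return (self.contig_a, self.side_a, self.contig_b, self.side_b)

    @property
    def relative_orientation(self) -> str:
        return "forward" if self.side_a != self.side_b else "reverse"


def bundle_links(links: Iterable[Link], min_support: int = 2) -> list[BundledEdge]:
    """Group links by junction; keep groups with enough support.

    The bundle gap estimate is the (low) median of member gap estimates.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    groups: dict[tuple, list[Link]] = {}
    for link in links:
        groups.setdefault(link.key, []).append(link)
    bundles = []
    for n, key in enumerate(sorted(groups)):
        members = groups[key]
        if len(members) < min_support:
            continue
        bundles.append(
            BundledEdge(
                edge_id=f"edge_{key[0]}.{key[1]}--{key[2]}.{key[3]}",
                contig_a=key[0], side_a=key[1],
                contig_b=key[2], side_b=key[3],
                gap_estimate=int(median_low(l.gap_estimate for l in members)),
                links=sorted(members, key=lambda l: (l.join_id, l.read_start)),
            )
        )
    return bundles
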