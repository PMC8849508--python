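"""Per-junction patch construction.

Each bundled edge carries the read intervals that span its junction.
In read modes those intervals are reduced to a single consensus
sequence by aligning every interval to a median-length template and
taking a per-column majority vote (deletions vote; insertions are
voted as strings between columns). In ``asm`` mode the single
supporting interval is used verbatim.

Patches are then re-anchored onto their two flanking contigs to fix
the junction trim points, and short contigs uniquely contained in a
patch are absorbed into it.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from statistics import median_low
from typing import Iterable, Mapping

from Bio import Align

from .align import BundledEdge, DEFAULT_ANCHOR_BP, DEFAULT_MAX_OVERHANG
from .io import SequenceRecord, revcomp

log = logging.getLogger(__name__)

# members this dissimilar to the template are dropped before voting
MIN_MEMBER_IDENTITY = 0.5
ANCHOR_MIN_IDENTITY = 0.95
CONTAINMENT_IDENTITY = 0.95
CONTAINMENT_COVERAGE = 0.95


def _aligner(local: bool) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -4
    a.extend_gap_score = -2
    if local:
        a.mode = "local"
    else:
        a.mode = "global"
        a.end_gap_score = 0  # free end gaps: intervals may differ at the ends
    return a


_GLOBAL = _aligner(local=False)
_LOCAL = _aligner(local=True)


def _best_alignment(aligner: Align.PairwiseAligner, target: str, query: str):
    alns = aligner.align(target, query)
    return alns[0]


def alignment_stats(aln) -> tuple[int, int]:
    """(matching columns, total aligned columns incl. internal gaps)."""
    counts = aln.counts()
    total = counts.identities + counts.mismatches + counts.internal_gaps
    return counts.identities, total


def pairwise_identity(a: str, b: str, local: bool = False) -> float:
    """Fraction of matching columns in the best pairwise alignment."""
    if not a or not b:
        return 0.0
    aln = _best_alignment(_LOCAL if local else _GLOBAL, a, b)
    matches, total = alignment_stats(aln)
    return matches / total if total else 0.0


@dataclass
class Patch:
    """A junction fill candidate between two contig ends.

    ``seq`` includes up to ``anchor_bp + max_overhang`` of contig-end
    sequence on each side; after anchoring, ``fill`` is the part that
    actually goes between the (possibly trimmed) contig ends.
    """

    edge_id: str
    contig_a: str
    side_a: str
    contig_b: str
    side_b: str
    gap_estimate: int
    seq: str | None
    support: int
    join_ids: frozenset[str] = frozenset()
    left_trim: int = 0
    right_trim: int = 0
    cut_left: int = 0
    cut_right: int = 0
    anchored: bool = False
    demote_reason: str | None = None

    @property
    def fill(self) -> str | None:
        """Junction sequence, or None when the gap stays unfilled."""
        if self.seq is None or not self.anchored:
            return None
        return self.seq[self.cut_left : self.cut_right]

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.contig_a, self.side_a, self.contig_b, self.side_b)


def _member_intervals(
    bundle: BundledEdge, reads: Mapping[str, SequenceRecord]
) -> list[tuple[str, str]]:
    """(join id, junction interval oriented a->b) per supporting link."""
    out = []
    for link in bundle.links:
        read = reads.get(link.join_id)
        if read is None:
            raise KeyError(f"missing joining sequence {link.join_id!r}")
        seq = read.seq[link.read_start : link.read_end]
        if link.flipped:
            seq = revcomp(seq)
        if seq:
            out.append((link.join_id, seq))
    return out


def _pick_template(intervals: list[tuple[str, str]]) -> tuple[str, str]:
    target = median_low(len(seq) for _, seq in intervals)
    return min(
        (iv for iv in intervals if len(iv[1]) == target),
        key=lambda iv: iv[0],
    )


def _vote_consensus(template: str, others: list[str]) -> str:
    """Majority vote over template columns and insertion slots."""
    t_len = len(template)
    col_votes: list[Counter] = [Counter() for _ in range(t_len)]
    ins_votes: list[Counter] = [Counter() for _ in range(t_len + 1)]
    cov_start = [0] * (t_len + 1)  # span coverage via difference array

    def add_read(t_blocks, q_blocks, qseq: str) -> None:
        span_lo, span_hi = int(t_blocks[0][0]), int(t_blocks[-1][1])
        cov_start[span_lo] += 1
        if span_hi < t_len + 1:
            cov_start[span_hi] -= 1
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            for i in range(te - ts):
                col_votes[ts + i][qseq[qs + i]] += 1
        for k in range(len(t_blocks) - 1):
            t_gap = int(t_blocks[k + 1][0]) - int(t_blocks[k][1])
            q_gap = int(q_blocks[k + 1][0]) - int(q_blocks[k][1])
            t_pos, q_pos = int(t_blocks[k][1]), int(q_blocks[k][1])
            paired = min(t_gap, q_gap)
            for i in range(paired):  # rare double-gap: pair residues 1:1
                col_votes[t_pos + i][qseq[q_pos + i]] += 1
            if t_gap > paired:
                for i in range(paired, t_gap):
                    col_votes[t_pos + i]["-"] += 1
            if q_gap > paired:
                ins_votes[t_pos + t_gap][qseq[q_pos + paired : q_pos + q_gap]] += 1

    # the template is itself a supporting interval and votes for itself
    add_read([(0, t_len)], [(0, t_len)], template)
    for qseq in others:
        aln = _best_alignment(_GLOBAL, template, qseq)
        t_blocks, q_blocks = aln.aligned
        if len(t_blocks) == 0:
            continue
        add_read(t_blocks, q_blocks, qseq)

    coverage = []
    running = 0
    for pos in range(t_len + 1):
        running += cov_start[pos]
        coverage.append(running)

    out: list[str] = []
    for pos in range(t_len + 1):
        votes = ins_votes[pos]
        if votes:
            string, count = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
            cov = max(coverage[pos], 1)
            if count > cov / 2:
                out.append(string)
        if pos < t_len:
            column = col_votes[pos]
            if column:
                top = max(column.values())
                winners = sorted(s for s, c in column.items() if c == top)
                pick = template[pos] if template[pos] in winners else winners[0]
            else:
                pick = template[pos]
            if pick != "-":
                out.append(pick)
    return "".join(out)


def build_patch(
    bundle: BundledEdge,
    reads: Mapping[str, SequenceRecord],
    mode: str,
    min_support: int = 2,
) -> Patch:
    """Consensus (read modes) or verbatim (asm mode) junction sequence."""
    intervals = _member_intervals(bundle, reads)
    base = dict(
        edge_id=bundle.edge_id,
        contig_a=bundle.contig_a,
        side_a=bundle.side_a,
        contig_b=bundle.contig_b,
        side_b=bundle.side_b,
        gap_estimate=bundle.gap_estimate,
        join_ids=bundle.join_ids,
    )
    if not intervals:
        return Patch(seq=None, support=0, demote_reason="no_spanning_sequence", **base)
    if mode == "asm":
        _, seq = _pick_template(intervals)
        return Patch(seq=seq, support=len(intervals), **base)

    _, template = _pick_template(intervals)
    kept: list[str] = []
    for join_id, seq in intervals:
        if seq == template:
            kept.append(seq)
            continue
        if pairwise_identity(template, seq) >= MIN_MEMBER_IDENTITY:
            kept.append(seq)
    if len(kept) < min_support:
        return Patch(
            seq=None, support=len(kept), demote_reason="support_below_minimum", **base
        )
    others = list(kept)
    others.remove(template)
    seq = _vote_consensus(template, others) if others else template
    return Patch(seq=seq, support=len(kept), **base)


# ---------------------------------------------------------------------------
# Re-anchoring on the flanking contigs
# ---------------------------------------------------------------------------


def _oriented_flank(contig: SequenceRecord, side: str, left_flank: bool) -> str:
    """Contig sequence oriented so the junction-facing end is to the
    right (left flank) or to the left (right flank)."""
    if left_flank:
        return contig.seq if side == "end" else revcomp(contig.seq)
    return contig.seq if side == "begin" else revcomp(contig.seq)


def _anchor_one_side(
    window: str, probe: str, *, window_at_end: bool
) -> tuple[int, int, float] | None:
    """Locally align probe to window; returns (contig trim, probe cut,
    identity) or None when no alignment is found."""
    if not window or not probe:
        return None
    aln = _best_alignment(_LOCAL, window, probe)
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    matches, total = alignment_stats(aln)
    identity = matches / total if total else 0.0
    if window_at_end:  # left flank: trim past the alignment end
        trim = len(window) - int(t_blocks[-1][1])
        cut = int(q_blocks[-1][1])
    else:  # right flank: trim before the alignment start
        trim = int(t_blocks[0][0])
        cut = int(q_blocks[0][0])
    return trim, cut, identity


def realign_patches(
    patches: Iterable[Patch],
    contigs: Mapping[str, SequenceRecord],
    anchor_bp: int = DEFAULT_ANCHOR_BP,
    max_overhang: int = DEFAULT_MAX_OVERHANG,
) -> list[Patch]:
    """Fix trim points by aligning each patch back onto its two flanks.

    Patches that fail to anchor at >=``ANCHOR_MIN_IDENTITY`` on either
    flank, or whose implied trim exceeds ``max_overhang``, are demoted
    to unfilled gaps (the scaffold link itself is kept).
    """
    window_len = anchor_bp + max_overhang + 200
    out: list[Patch] = []
    for patch in patches:
        if patch.seq is None:
            out.append(patch)
            continue
        left = contigs[patch.contig_a]
        right = contigs[patch.contig_b]
        lseq = _oriented_flank(left, patch.side_a, left_flank=True)
        rseq = _oriented_flank(right, patch.side_b, left_flank=False)
        head = patch.seq[:window_len]
        tail = patch.seq[-window_len:]
        res_l = _anchor_one_side(lseq[-window_len:], head, window_at_end=True)
        res_r = _anchor_one_side(rseq[:window_len], tail, window_at_end=False)
        if res_l is None or res_r is None:
            patch.anchored = False
            patch.demote_reason = "anchor_failed"
            out.append(patch)
            continue
        ltrim, lcut, lident = res_l
        rtrim, rcut_tail, rident = res_r
        rcut = len(patch.seq) - len(tail) + rcut_tail
        if lident < ANCHOR_MIN_IDENTITY or rident < ANCHOR_MIN_IDENTITY:
            patch.anchored = False
            patch.demote_reason = "anchor_identity"
            out.append(patch)
            continue
        if rcut < lcut:  # negative gap: contig ends overlap on the patch
            rtrim += lcut - rcut
            rcut = lcut
        if ltrim > max_overhang or rtrim > max_overhang:
            patch.anchored = False
            patch.demote_reason = "trim_exceeds_overhang"
            out.append(patch)
            continue
        patch.left_trim = ltrim
        patch.right_trim = rtrim
        patch.cut_left = lcut
        patch.cut_right = rcut
        patch.anchored = True
        patch.demote_reason = None
        out.append(patch)
    return out


# ---------------------------------------------------------------------------
# Contained-contig absorption
# ---------------------------------------------------------------------------


def absorb_contained_contigs(
    patches: list[Patch],
    contigs: Mapping[str, SequenceRecord],
    candidate_ids: Iterable[str] | None = None,
) -> tuple[list[Patch], list[str]]:
    """Splice contigs uniquely contained in one patch into that patch.

    A candidate contig (shorter than the longest patch) is absorbed when
    it aligns to exactly one patch at >95% identity over >95% of its
    length; its aligned portion replaces the corresponding patch
    interval and its id is reported for removal from the output.
    Contigs contained in two or more patches are left untouched.
    """
    live = [p for p in patches if p.seq]
    if not live:
        return patches, []
    max_patch = max(len(p.seq) for p in live)
    if candidate_ids is None:
        candidate_ids = contigs.keys()
    candidates = sorted(
        cid for cid in candidate_ids if contigs[cid].length < max_patch
    )
    hits: dict[str, list[tuple[Patch, int, int, str]]] = {}
    for cid in candidates:
        cseq = contigs[cid].seq
        for patch in live:
            if len(patch.seq) <= len(cseq):
                continue
            best = None
            for oriented in (cseq, revcomp(cseq)):
                aln = _best_alignment(_LOCAL, patch.seq, oriented)
                t_blocks, q_blocks = aln.aligned
                if len(t_blocks) == 0:
                    continue
                matches, total = alignment_stats(aln)
                identity = matches / total if total else 0.0
                covered = int(q_blocks[-1][1]) - int(q_blocks[0][0])
                cand = (identity, covered, int(t_blocks[0][0]), int(t_blocks[-1][1]), oriented)
                if best is None or cand[:2] > best[:2]:
                    best = cand
            if best is None:
                continue
            identity, covered, t_lo, t_hi, oriented = best
            if identity > CONTAINMENT_IDENTITY and covered > CONTAINMENT_COVERAGE * len(cseq):
                hits.setdefault(cid, []).append((patch, t_lo, t_hi, oriented))
    removed: list[str] = []
    for cid, placements in sorted(hits.items()):
        if len(placements) != 1:
            log.info("contig %s contained in %d patches; kept standalone", cid, len(placements))
            continue
        patch, t_lo, t_hi, oriented = placements[0]
        patch.seq = patch.seq[:t_lo] + oriented + patch.seq[t_hi:]
        patch.anchored = False  # trims must be re-derived after splicing
        removed.append(cid)
    return patches, removed
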