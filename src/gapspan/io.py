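"""Sequence and alignment input/output.

Reads FASTA/FASTQ (optionally gzipped) into :class:`SequenceRecord`,
parses/writes PAF alignment tables, and emits the final scaffold
artifacts: FASTA, AGP v2.1 and a per-junction TSV report.

All coordinates are 0-based half-open internally; the AGP writer converts
to AGP's 1-based inclusive convention at the boundary.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")

# Unfilled gap lengths written to FASTA/AGP are clamped to this range.
MIN_GAP_RUN = 100
MAX_GAP_RUN = 1_000_000


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ/PAF input."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (a contig or a joining sequence)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record with empty id")
        if not self.seq:
            raise ParseError(f"sequence record {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentRecord:
    """One PAF row (12 mandatory columns; tags are dropped on parse)."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_len: int
    mapq: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ParseError(f"bad strand {self.strand!r}")
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ParseError(
                f"bad query interval {self.query_start}-{self.query_end} "
                f"for {self.query_id!r} (len {self.query_len})"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ParseError(
                f"bad target interval {self.target_start}-{self.target_end} "
                f"for {self.target_id!r} (len {self.target_len})"
            )
        if self.matches > self.block_len:
            raise ParseError(
                f"matches {self.matches} exceed block length {self.block_len}"
            )


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _clean_seq(raw: str, rec_id: str) -> str:
    seq = raw.upper()
    if not set(seq) <= _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        log.warning(
            "record %s: mapping non-ACGTN letters %s to N", rec_id, "".join(bad)
        )
        seq = "".join(c if c in _ALPHABET else "N" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA or FASTQ (auto-detected, gzip ok) into records.

    Sequences are uppercased, non-ACGTN letters become N, and the id is
    truncated at the first whitespace. Duplicate ids are an error.
    """
    handle = _open_maybe_gzip(path)
    with handle:
        first = handle.read(1)
        handle.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        elif first == "":
            return []
        else:
            raise ParseError(
                f"{path}: line 1: expected '>' (FASTA) or '@' (FASTQ), "
                f"got {first!r}"
            )
        records: list[SequenceRecord] = []
        seen: set[str] = set()
        try:
            for rec in SeqIO.parse(handle, fmt):
                if rec.id in seen:
                    raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
                seen.add(rec.id)
                records.append(SequenceRecord(rec.id, _clean_seq(str(rec.seq), rec.id)))
        except ValueError as exc:  # Biopython parse failures
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"{path}: record {len(records) + 1}: {exc}") from exc
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")


def parse_paf(source: str | Path | Iterable[str]) -> list[AlignmentRecord]:
    """Parse PAF lines (>=12 tab-separated columns; extra columns ignored)."""
    if isinstance(source, (str, Path)):
        with _open_maybe_gzip(source) as handle:
            return parse_paf(list(handle))
    records = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ParseError(
                f"PAF line {lineno}: expected >=12 columns, got {len(cols)}"
            )
        try:
            records.append(
                AlignmentRecord(
                    query_id=cols[0],
                    query_len=int(cols[1]),
                    query_start=int(cols[2]),
                    query_end=int(cols[3]),
                    strand=cols[4],
                    target_id=cols[5],
                    target_len=int(cols[6]),
                    target_start=int(cols[7]),
                    target_end=int(cols[8]),
                    matches=int(cols[9]),
                    block_len=int(cols[10]),
                    mapq=int(cols[11]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"PAF line {lineno}: {exc}") from exc
    return records


def write_paf(records: Iterable[AlignmentRecord], dest: str | Path | IO[str]) -> None:
    own = isinstance(dest, (str, Path))
    out = open(dest, "w") if own else dest
    try:
        for r in records:
            out.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.query_id,
                        r.query_len,
                        r.query_start,
                        r.query_end,
                        r.strand,
                        r.target_id,
                        r.target_len,
                        r.target_start,
                        r.target_end,
                        r.matches,
                        r.block_len,
                        r.mapq,
                    )
                )
                + "\n"
            )
    finally:
        if own:
            out.close()


# ---------------------------------------------------------------------------
# Scaffold emission
# ---------------------------------------------------------------------------


@dataclass
class GapFill:
    """What goes between two consecutive scaffold members.

    ``seq`` is the junction fill sequence (may be empty for abutting
    merges); ``None`` means the gap is spanned but unfilled and is
    written as an N run of the clamped estimated size. ``left_trim`` /
    ``right_trim`` are bases removed from the junction-facing ends of
    the left/right oriented members.
    """

    seq: str | None
    gap_estimate: int = 0
    left_trim: int = 0
    right_trim: int = 0
    support: int = 0
    patch_id: str = ""

    @property
    def n_run(self) -> int:
        return max(MIN_GAP_RUN, min(MAX_GAP_RUN, self.gap_estimate))


@dataclass
class ScaffoldLayout:
    """An ordered, oriented contig list with per-junction fills."""

    name: str
    members: list[tuple[str, str]]  # (contig id, '+'/'-')
    gaps: list[GapFill] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.gaps) != max(0, len(self.members) - 1):
            raise ValueError(
                f"scaffold {self.name}: {len(self.members)} members need "
                f"{len(self.members) - 1} gaps, got {len(self.gaps)}"
            )


def layout_sequence(layout: ScaffoldLayout, contigs: dict[str, SequenceRecord]) -> str:
    """Concatenate oriented, trimmed members and junction fills."""
    parts: list[str] = []
    for i, (cid, orient) in enumerate(layout.members):
        if cid not in contigs:
            raise KeyError(f"scaffold {layout.name}: missing contig sequence {cid!r}")
        seq = contigs[cid].seq
        if orient == "-":
            seq = revcomp(seq)
        start = layout.gaps[i - 1].right_trim if i > 0 else 0
        end = len(seq) - (layout.gaps[i].left_trim if i < len(layout.gaps) else 0)
        if start >= end:
            raise ValueError(
                f"scaffold {layout.name}: trims consume contig {cid} entirely"
            )
        parts.append(seq[start:end])
        if i < len(layout.gaps):
            gap = layout.gaps[i]
            parts.append(gap.seq if gap.seq is not None else "N" * gap.n_run)
    return "".join(parts)


def _agp_rows(
    layout: ScaffoldLayout, contigs: dict[str, SequenceRecord]
) -> Iterator[tuple]:
    pos = 0  # 0-based scaffold cursor
    part = 0
    for i, (cid, orient) in enumerate(layout.members):
        clen = contigs[cid].length
        start_cut = layout.gaps[i - 1].right_trim if i > 0 else 0
        end_cut = layout.gaps[i].left_trim if i < len(layout.gaps) else 0
        used = clen - start_cut - end_cut
        # map oriented trims back to forward-strand component coordinates
        if orient == "+":
            comp_beg, comp_end = start_cut + 1, clen - end_cut
        else:
            comp_beg, comp_end = end_cut + 1, clen - start_cut
        part += 1
        yield (layout.name, pos + 1, pos + used, part, "W", cid, comp_beg, comp_end, orient)
        pos += used
        if i < len(layout.gaps):
            gap = layout.gaps[i]
            if gap.seq is not None:
                if gap.seq:
                    part += 1
                    yield (
                        layout.name, pos + 1, pos + len(gap.seq), part, "W",
                        gap.patch_id or f"{layout.name}_patch{i}", 1, len(gap.seq), "+",
                    )
                    pos += len(gap.seq)
            else:
                part += 1
                yield (
                    layout.name, pos + 1, pos + gap.n_run, part, "N",
                    gap.n_run, "scaffold", "yes", "unspecified",
                )
                pos += gap.n_run


def write_scaffolds(
    layouts: Sequence[ScaffoldLayout],
    contigs: dict[str, SequenceRecord],
    out_fasta: str | Path,
    out_agp: str | Path,
) -> dict[str, int]:
    """Write scaffold FASTA and AGP v2.1; returns scaffold lengths."""
    lengths: dict[str, int] = {}
    with open(out_fasta, "w") as fa, open(out_agp, "w") as agp:
        agp.write("##agp-version\t2.1\n")
        for layout in layouts:
            seq = layout_sequence(layout, contigs)
            lengths[layout.name] = len(seq)
            fa.write(f">{layout.name}\n")
            for i in range(0, len(seq), 60):
                fa.write(seq[i : i + 60] + "\n")
            for row in _agp_rows(layout, contigs):
                agp.write("\t".join(str(v) for v in row) + "\n")
    return lengths


def read_agp_layouts(
    agp_path: str | Path,
    contig_ids: set[str],
    patch_seqs: dict[str, str] | None = None,
) -> list[ScaffoldLayout]:
    """Rebuild scaffold layouts from an AGP file.

    W components whose id is a known contig become members; other W
    components are treated as patch fills (sequence looked up in
    ``patch_seqs`` when available); N/U rows become unfilled gaps.
    Trim information is not recoverable and is left at zero.
    """
    patch_seqs = patch_seqs or {}
    per_scaffold: dict[str, list[tuple]] = {}
    order: list[str] = []
    with open(agp_path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            name = cols[0]
            if name not in per_scaffold:
                per_scaffold[name] = []
                order.append(name)
            per_scaffold[name].append(tuple(cols))
    layouts = []
    for name in order:
        members: list[tuple[str, str]] = []
        gaps: list[GapFill] = []
        pending: GapFill | None = None
        for cols in per_scaffold[name]:
            if cols[4] == "W" and cols[5] in contig_ids:
                if members:
                    gaps.append(pending if pending is not None else GapFill(seq=""))
                pending = None
                members.append((cols[5], cols[8]))
            elif cols[4] == "W":
                pending = GapFill(
                    seq=patch_seqs.get(cols[5], "N" * (int(cols[2]) - int(cols[1]) + 1)),
                    patch_id=cols[5],
                )
            else:  # N or U gap row
                pending = GapFill(seq=None, gap_estimate=int(cols[5]))
        layouts.append(ScaffoldLayout(name, members, gaps))
    return layouts


def write_junction_report(
    layouts: Sequence[ScaffoldLayout], path: str | Path
) -> None:
    """TSV of every junction: members, orientations, gap, fill, support."""
    header = (
        "scaffold\tleft_contig\tleft_orient\tright_contig\tright_orient\t"
        "gap_estimate\tpatch_len\tleft_trim\tright_trim\tsupport\tstatus\n"
    )
    with open(path, "w") as out:
        out.write(header)
        for layout in layouts:
            for i, gap in enumerate(layout.gaps):
                (lc, lo), (rc, ro) = layout.members[i], layout.members[i + 1]
                status = "filled" if gap.seq is not None else "unfilled"
                plen = len(gap.seq) if gap.seq is not None else gap.n_run
                out.write(
                    f"{layout.name}\t{lc}\t{lo}\t{rc}\t{ro}\t{gap.gap_estimate}\t"
                    f"{plen}\t{gap.left_trim}\t{gap.right_trim}\t{gap.support}\t"
                    f"{status}\n"
                )
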