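"""Synthetic genomes, fragmented assemblies and long reads with known
truth, plus truth-based scaffold evaluation.

All generators are deterministic given a seed. The truth table records
contig placements (a contig id may be placed at several loci when
repeat collapsing is simulated), repeat annotations and read
placements, and is written/read as a versioned TSV.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import SequenceRecord, revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")

TRUTH_FORMAT_VERSION = 1


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ContigPlacement:
    contig_id: str
    start: int
    end: int
    orient: str  # orientation of the contig relative to the genome


@dataclass(frozen=True)
class ReadPlacement:
    read_id: str
    start: int
    end: int
    strand: str
    error_rate: float


@dataclass
class SimTruth:
    genome: SequenceRecord
    contig_placements: list[ContigPlacement] = field(default_factory=list)
    repeats: list[tuple[int, int, int]] = field(default_factory=list)  # start, end, group
    read_placements: list[ReadPlacement] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _mutate_to_identity(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Apply substitutions at rate (1 - identity)."""
    if identity >= 1.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < (1.0 - identity))[0]
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(len(choices))]])
    return arr.tobytes().decode()


def simulate_genome(
    length: int,
    repeat_count: int = 0,
    repeat_len: int = 0,
    repeat_identity: float = 1.0,
    seed: int = 0,
) -> SimTruth:
    """Uniform random genome with optional interspersed repeat copies."""
    if repeat_count and repeat_len * repeat_count >= length / 2:
        raise SimulationError("repeats would occupy more than half the genome")
    rng = np.random.default_rng(seed)
    genome = list(_random_seq(rng, length))
    repeats: list[tuple[int, int, int]] = []
    if repeat_count:
        unit = _random_seq(rng, repeat_len)
        margin = 200  # keep copies apart and off the genome ends
        placed: list[int] = []
        for _ in range(10_000):
            if len(placed) == repeat_count:
                break
            pos = int(rng.integers(margin, length - repeat_len - margin))
            if all(abs(pos - p) >= repeat_len + margin for p in placed):
                placed.append(pos)
        if len(placed) < repeat_count:
            raise SimulationError("could not place repeat copies; genome too small")
        for start in sorted(placed):
            copy = _mutate_to_identity(rng, unit, repeat_identity)
            genome[start : start + repeat_len] = copy
            repeats.append((start, start + repeat_len, 0))
    return SimTruth(
        genome=SequenceRecord("genome", "".join(genome)),
        repeats=repeats,
    )


def _segment_cuts(
    rng: np.random.Generator, lo: int, hi: int, n_pieces: int, gap_range: tuple[int, int]
) -> list[tuple[int, int]]:
    """Tile [lo, hi) with n_pieces intervals separated by random gaps."""
    span = hi - lo
    gaps = [int(rng.integers(gap_range[0], gap_range[1] + 1)) for _ in range(n_pieces - 1)]
    remaining = span - sum(gaps)
    if remaining < n_pieces * 50:
        raise SimulationError(
            f"cannot fit {n_pieces} contigs with gaps {gap_range} into {span} bp"
        )
    weights = 0.7 + 0.6 * rng.random(n_pieces)
    lens = np.floor(remaining * weights / weights.sum()).astype(int)
    lens[-1] += remaining - int(lens.sum())
    pieces = []
    pos = lo
    for i in range(n_pieces):
        pieces.append((pos, pos + int(lens[i])))
        pos += int(lens[i])
        if i < n_pieces - 1:
            pos += gaps[i]
    return pieces


def fragment_genome(
    truth: SimTruth,
    n_contigs: int,
    gap_range: tuple[int, int],
    seed: int = 0,
    revcomp_fraction: float = 0.0,
    end_perturb_bp: int = 0,
    collapse_repeats: bool = False,
) -> list[SequenceRecord]:
    """Cut the genome into gapped contigs; updates truth placements.

    With ``collapse_repeats`` each annotated repeat group is emitted as
    a single contig (from its first copy) placed at every copy locus,
    emulating an assembly that collapsed the repeat; the flanking
    regions are tiled normally.
    """
    rng = np.random.default_rng(seed)
    genome = truth.genome.seq
    g_len = len(genome)
    regions: list[tuple[int, int, str | None]] = []  # (start, end, forced contig id)
    if collapse_repeats and truth.repeats:
        groups: dict[int, str] = {}
        pos = 0
        free_spans: list[tuple[int, int]] = []
        for start, end, group in sorted(truth.repeats):
            free_spans.append((pos, start))
            cid = groups.get(group)
            if cid is None:
                cid = f"repeat_g{group}"
                groups[group] = cid
            regions.append((start, end, cid))
            pos = end
        free_spans.append((pos, g_len))
        n_free = max(1, n_contigs - len(groups))
        spans = [(a, b) for a, b in free_spans if b - a > 2 * (gap_range[1] + 100)]
        total_free = sum(b - a for a, b in spans)
        for a, b in spans:
            pieces = max(1, round(n_free * (b - a) / total_free))
            # carve a gap against each adjacent repeat boundary
            lo = a + (gap_range[0] if a > 0 else 0)
            hi = b - (gap_range[0] if b < g_len else 0)
            for s, e in _segment_cuts(rng, lo, hi, pieces, gap_range):
                regions.append((s, e, None))
        regions.sort()
    else:
        if n_contigs < 1:
            raise SimulationError("need at least one contig")
        regions = [(s, e, None) for s, e in _segment_cuts(rng, 0, g_len, n_contigs, gap_range)]

    contigs: list[SequenceRecord] = []
    emitted: set[str] = set()
    counter = 0
    for start, end, forced in regions:
        if forced is not None:
            if forced in emitted:
                truth.contig_placements.append(ContigPlacement(forced, start, end, "+"))
                continue
            cid = forced
        else:
            counter += 1
            cid = f"contig_{counter:03d}"
        orient = "-" if rng.random() < revcomp_fraction else "+"
        seq = genome[start:end]
        if orient == "-":
            seq = revcomp(seq)
        truth.contig_placements.append(ContigPlacement(cid, start, end, orient))
        contigs.append(SequenceRecord(cid, seq))
        emitted.add(cid)
    if end_perturb_bp:
        contigs = _perturb_ends(rng, contigs, truth, min(end_perturb_bp, 1000))
    truth.contig_placements.sort(key=lambda p: (p.start, p.contig_id))
    return contigs


def _perturb_ends(
    rng: np.random.Generator,
    contigs: list[SequenceRecord],
    truth: SimTruth,
    perturb: int,
) -> list[SequenceRecord]:
    """Append shuffled sequence to junction-facing contig ends."""
    placements = {p.contig_id: p for p in truth.contig_placements}
    g_len = truth.genome.length
    out = []
    for rec in contigs:
        p = placements[rec.id]
        seq = rec.seq
        left_junk = _random_seq(rng, perturb) if p.start > 0 else ""
        right_junk = _random_seq(rng, perturb) if p.end < g_len else ""
        if p.orient == "-":
            left_junk, right_junk = right_junk, left_junk
        out.append(SequenceRecord(rec.id, left_junk + seq + right_junk))
    return out


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out: list[str] = []
    bases = "ACGT"
    for ch in seq:
        if rng.random() < rate:
            kind = rng.integers(3)
            if kind == 0:  # substitution
                out.append([b for b in bases if b != ch][int(rng.integers(3))])
            elif kind == 1:  # insertion
                out.append(ch)
                out.append(bases[int(rng.integers(4))])
            # kind == 2: deletion -> emit nothing
        else:
            out.append(ch)
    return "".join(out)


def simulate_reads(
    truth: SimTruth,
    coverage: float,
    read_len_mean: int,
    error_rate: float = 0.0,
    seed: int = 0,
    read_len_sigma: float = 0.15,
) -> list[SequenceRecord]:
    """Log-normal read lengths, uniform starts, i.i.d. 1:1:1 sub/ins/del
    errors, random strand; updates truth read placements."""
    rng = np.random.default_rng(seed)
    genome = truth.genome.seq
    g_len = len(genome)
    n_reads = max(1, round(coverage * g_len / read_len_mean))
    mu = math.log(read_len_mean) - read_len_sigma**2 / 2
    reads: list[SequenceRecord] = []
    i = 0
    while len(reads) < n_reads:
        i += 1
        if i > 20 * n_reads:
            raise SimulationError("read sampling failed to converge")
        start = int(rng.integers(0, g_len))
        length = int(rng.lognormal(mu, read_len_sigma))
        end = min(g_len, start + max(length, 1))
        if end - start < 200:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        rid = f"read_{len(reads):05d}"
        seq = _apply_errors(rng, genome[start:end], error_rate)
        if strand == "-":
            seq = revcomp(seq)
        reads.append(SequenceRecord(rid, seq))
        truth.read_placements.append(ReadPlacement(rid, start, end, strand, error_rate))
    return reads


# ---------------------------------------------------------------------------
# Truth table round-trip
# ---------------------------------------------------------------------------


def write_truth(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write(f"#truth_version\t{TRUTH_FORMAT_VERSION}\n")
        out.write(f"#genome_length\t{truth.genome.length}\n")
        for p in truth.contig_placements:
            out.write(f"contig\t{p.contig_id}\t{p.start}\t{p.end}\t{p.orient}\n")
        for start, end, group in truth.repeats:
            out.write(f"repeat\t{start}\t{end}\t{group}\n")
        for r in truth.read_placements:
            out.write(
                f"read\t{r.read_id}\t{r.start}\t{r.end}\t{r.strand}\t{r.error_rate}\n"
            )


def read_truth(path: str | Path, genome: SequenceRecord) -> SimTruth:
    truth = SimTruth(genome=genome)
    with open(path) as handle:
        for line in handle:
            cols = line.rstrip("\n").split("\t")
            if cols[0] == "contig":
                truth.contig_placements.append(
                    ContigPlacement(cols[1], int(cols[2]), int(cols[3]), cols[4])
                )
            elif cols[0] == "repeat":
                truth.repeats.append((int(cols[1]), int(cols[2]), int(cols[3])))
            elif cols[0] == "read":
                truth.read_placements.append(
                    ReadPlacement(cols[1], int(cols[2]), int(cols[3]), cols[4], float(cols[5]))
                )
    return truth


# ---------------------------------------------------------------------------
# Contiguity statistics and truth-based evaluation
# ---------------------------------------------------------------------------


def nx_stat(lengths: Sequence[int], fraction: float, total: int | None = None) -> int:
    """Smallest length L such that sequences >= L cover ``fraction`` of
    ``total`` (default: the summed lengths). N50 is fraction=0.5."""
    if not lengths:
        return 0
    if total is None:
        total = sum(lengths)
    threshold = fraction * total
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= threshold:
            return length
    return min(lengths)


def n50(lengths: Sequence[int]) -> int:
    return nx_stat(lengths, 0.5)


def ng50(lengths: Sequence[int], genome_size: int) -> int:
    return nx_stat(lengths, 0.5, total=genome_size)


def n90(lengths: Sequence[int]) -> int:
    return nx_stat(lengths, 0.9)


@dataclass
class EvalReport:
    genome_coverage: float
    misjoins: int
    junctions: int
    true_junctions: int
    patch_error_rate: float | None
    n50: int
    ng50: int
    max_scaffold: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            for key, val in vars(self).items():
                out.write(f"{key}\t{val}\n")


def _gap_interval(truth: SimTruth, left: str, right: str) -> tuple[int, int, bool] | None:
    """True genome gap between two adjacent contigs, plus whether the
    (left, right) order traverses the genome forward."""
    placed = sorted(truth.contig_placements, key=lambda p: p.start)
    for a, b in zip(placed, placed[1:]):
        if {a.contig_id, b.contig_id} == {left, right}:
            return (a.end, b.start, a.contig_id == left)
    return None


def evaluate(
    layouts,
    truth: SimTruth,
    patch_fills: dict[tuple[str, str], str] | None = None,
) -> EvalReport:
    """Score scaffold layouts against the simulation truth.

    ``layouts`` are :class:`gapspan.io.ScaffoldLayout`; junctions whose
    oriented contig pair is not adjacent in the truth count as
    mis-joins. Patch error is the mean alignment error of each filled
    junction against its true gap sequence.
    """
    true_adj = _layout_adjacencies(truth)
    placements: dict[str, list[ContigPlacement]] = {}
    for p in truth.contig_placements:
        placements.setdefault(p.contig_id, []).append(p)

    misjoins = 0
    junctions = 0
    covered = np.zeros(truth.genome.length, dtype=bool)
    patch_errors: list[float] = []
    lengths = []
    for layout in layouts:
        total_len = 0
        for cid, _ in layout.members:
            for p in placements.get(cid, []):
                covered[p.start : p.end] = True
            if cid in placements:
                p0 = placements[cid][0]
                total_len += p0.end - p0.start
        for i, gap in enumerate(layout.gaps):
            junctions += 1
            (lc, lo), (rc, ro) = layout.members[i], layout.members[i + 1]
            if (lc, lo, rc, ro) not in true_adj:
                misjoins += 1
                continue
            interval = _gap_interval(truth, lc, rc)
            if interval is not None:
                lo_g, hi_g, forward = interval
                covered[lo_g:hi_g] = True
                if gap.seq is not None:
                    true_gap = truth.genome.seq[lo_g:hi_g]
                    fill = gap.seq if forward else revcomp(gap.seq)
                    patch_errors.append(_patch_error(fill, true_gap))
            total_len += len(gap.seq) if gap.seq is not None else gap.n_run
        lengths.append(total_len)

    return EvalReport(
        genome_coverage=float(covered.mean()) if truth.genome.length else 0.0,
        misjoins=misjoins,
        junctions=junctions,
        true_junctions=max(0, len(truth.contig_placements) - 1),
        patch_error_rate=(sum(patch_errors) / len(patch_errors)) if patch_errors else None,
        n50=n50(lengths),
        ng50=ng50(lengths, truth.genome.length),
        max_scaffold=max(lengths, default=0),
    )


def _layout_adjacencies(truth: SimTruth) -> set[tuple[str, str, str, str]]:
    """True oriented junctions expressed in contig-local orientations.

    A scaffold member orientation o means the contig appears
    reverse-complemented when o == '-'; a junction (a, oa) -> (b, ob)
    is true when composing each member orientation with its truth
    placement orientation reproduces a genome adjacency in either
    direction.
    """
    placed = sorted(truth.contig_placements, key=lambda p: p.start)
    out = set()
    for a, b in zip(placed, placed[1:]):
        # scaffold traverses genome forward:
        out.add((a.contig_id, a.orient, b.contig_id, b.orient))
        flip = {"+": "-", "-": "+"}
        out.add((b.contig_id, flip[b.orient], a.contig_id, flip[a.orient]))
    return out


def _patch_error(patch_seq: str, true_seq: str) -> float:
    from .consensus import _best_alignment, _GLOBAL, alignment_stats

    if not true_seq and not patch_seq:
        return 0.0
    if not true_seq or not patch_seq:
        return 1.0
    aln = _best_alignment(_GLOBAL, true_seq, patch_seq)
    matches, total = alignment_stats(aln)
    denom = max(len(true_seq), len(patch_seq))
    return max(0.0, 1.0 - matches / denom)
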