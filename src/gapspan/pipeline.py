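"""End-to-end orchestration: align, filter, bundle, consensus, anchor,
resolve the contig graph, absorb contained contigs, and emit outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

from . import align as al
from . import consensus as cons
from . import graph as gr
from .io import (
    GapFill,
    ScaffoldLayout,
    SequenceRecord,
    parse_paf,
    read_fasta,
    revcomp,
    write_fasta,
    write_junction_report,
    write_scaffolds,
)
from .simdata import n90

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    assembly: str
    joins: str
    mode: str = "ont"
    min_aln_len: int = al.DEFAULT_MIN_ALN_LEN
    max_overhang: int = al.DEFAULT_MAX_OVERHANG
    min_support: int | None = None  # default: 2 in read modes, 1 in asm
    anchor_bp: int = al.DEFAULT_ANCHOR_BP
    threads: int = 1
    seed: int = 0
    out_prefix: str = "gapspan"
    paf: str | None = None
    split_at_n: bool = False
    resume: bool = True

    def validate(self) -> None:
        if self.mode not in ("ont", "pbclr", "asm"):
            raise ConfigError(f"mode must be ont/pbclr/asm, got {self.mode!r}")
        for path, what in ((self.assembly, "assembly"), (self.joins, "joins")):
            if not Path(path).exists():
                raise ConfigError(f"{what} file not found: {path}")
        if self.paf is not None and not Path(self.paf).exists():
            raise ConfigError(f"PAF file not found: {self.paf}")
        for name in ("min_aln_len", "max_overhang", "anchor_bp", "threads"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.min_support is not None and self.min_support < 1:
            raise ConfigError("min_support must be >= 1")

    @property
    def effective_min_support(self) -> int:
        if self.min_support is not None:
            return self.min_support
        return al.default_min_support(self.mode)


@dataclass
class RunResult:
    layouts: list[ScaffoldLayout]
    contigs: dict[str, SequenceRecord]
    patches: list[cons.Patch]
    removed_haplotigs: list[str]
    absorbed: list[str]
    repeat_insertions: dict[str, int]
    counts: dict[str, int]
    accounting: dict[str, int]
    outputs: dict[str, str]
    warnings: list[str] = field(default_factory=list)


def _split_at_n(records: list[SequenceRecord], min_run: int = 10) -> list[SequenceRecord]:
    import re

    out = []
    for rec in records:
        parts = [p for p in re.split(f"N{{{min_run},}}", rec.seq) if p]
        if len(parts) == 1:
            out.append(rec)
        else:
            out.extend(
                SequenceRecord(f"{rec.id}_part{i + 1}", p) for i, p in enumerate(parts)
            )
    return out


def _file_digest(*paths: str) -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def _cached_alignment(config: RunConfig, out_paf: Path) -> Path:
    """Run minimap2 unless a cached PAF for identical inputs exists."""
    meta_path = Path(str(out_paf) + ".meta")
    digest = _file_digest(config.assembly, config.joins) + f":{config.mode}"
    if config.resume and out_paf.exists() and meta_path.exists():
        try:
            if json.loads(meta_path.read_text()).get("digest") == digest:
                log.info("reusing cached alignment %s", out_paf)
                return out_paf
        except (json.JSONDecodeError, OSError):
            pass
    al.run_aligner(config.assembly, config.joins, config.mode, config.threads, out_paf)
    meta_path.write_text(json.dumps({"digest": digest}))
    return out_paf


def _junction_gapfill(
    patch: cons.Patch, left: tuple[str, str], right: tuple[str, str]
) -> GapFill:
    """Orient a patch payload for a junction traversed left-to-right."""
    (lc, lo), (rc, ro) = left, right
    fl = "end" if lo == "+" else "begin"
    fr = "begin" if ro == "+" else "end"
    forward = (lc, fl) == (patch.contig_a, patch.side_a) and (rc, fr) == (
        patch.contig_b,
        patch.side_b,
    )
    fill = patch.fill
    if fill is None:
        return GapFill(
            seq=None,
            gap_estimate=patch.gap_estimate,
            support=patch.support,
            patch_id=patch.edge_id,
        )
    if forward:
        return GapFill(
            seq=fill,
            gap_estimate=patch.gap_estimate,
            left_trim=patch.left_trim,
            right_trim=patch.right_trim,
            support=patch.support,
            patch_id=patch.edge_id,
        )
    return GapFill(
        seq=revcomp(fill),
        gap_estimate=patch.gap_estimate,
        left_trim=patch.right_trim,
        right_trim=patch.left_trim,
        support=patch.support,
        patch_id=patch.edge_id,
    )


def _paths_to_layouts(
    paths: list[gr.ScaffoldPath], patch_by_edge: dict[str, cons.Patch]
) -> list[ScaffoldLayout]:
    layouts = []
    for path in paths:
        gaps = []
        for i, payload in enumerate(path.fills):
            patch = patch_by_edge.get(getattr(payload, "edge_id", ""))
            if patch is None:  # hand-built graphs: payloads without patches
                gaps.append(
                    GapFill(
                        seq=None,
                        gap_estimate=getattr(payload, "gap_estimate", 0),
                        support=getattr(payload, "support", 0),
                    )
                )
            else:
                gaps.append(_junction_gapfill(patch, path.members[i], path.members[i + 1]))
        layouts.append(ScaffoldLayout("unnamed", list(path.members), gaps))
    # most members first, deterministic tie-break on first member id
    layouts.sort(key=lambda l: (-len(l.members), l.members[0][0]))
    for i, layout in enumerate(layouts, start=1):
        layout.name = f"scaffold_{i:04d}"
    return layouts


def run(config: RunConfig) -> RunResult:
    """Execute the full scaffolding pipeline and write all outputs."""
    config.validate()
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    counts: dict[str, int] = {}

    log_path = Path(f"{prefix}.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("gapspan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    outputs: dict[str, str] = {"log": str(log_path)}
    stage = "configure"
    try:
        log.info("run configuration: %s", config)

        stage = "load_inputs"
        contig_records = read_fasta(config.assembly)
        if config.split_at_n:
            contig_records = _split_at_n(contig_records)
        contigs = {c.id: c for c in contig_records}
        contig_n90 = n90([c.length for c in contig_records])
        counts["contigs_in"] = len(contig_records)
        if contig_n90 < config.min_aln_len:
            msg = (
                f"input assembly N90 ({contig_n90} bp) is below the minimum "
                f"alignment length ({config.min_aln_len} bp); scaffolding works "
                "best on relatively contiguous assemblies"
            )
            warnings.append(msg)
            log.warning(msg)
        joins = {r.id: r for r in read_fasta(config.joins)}
        counts["joins_in"] = len(joins)

        stage = "align"
        if config.paf is not None:
            paf_path = Path(config.paf)
        else:
            paf_path = _cached_alignment(config, Path(f"{prefix}.aln.paf"))
        alignments = parse_paf(paf_path)
        counts["alignments_in"] = len(alignments)

        stage = "filter"
        best = al.select_best(alignments)
        proper, _rejected = al.filter_proper(
            best, config.min_aln_len, config.max_overhang
        )
        counts["alignments_best"] = len(best)
        counts["alignments_proper"] = len(proper)
        links = al.extract_links(proper, config.anchor_bp, config.max_overhang)
        counts["links"] = len(links)
        bundles = al.bundle_links(links, config.effective_min_support)
        counts["bundles"] = len(bundles)
        if not bundles:
            msg = "no supported junctions found; output equals the input assembly"
            warnings.append(msg)
            log.warning(msg)

        stage = "consensus"
        patches = [
            cons.build_patch(b, joins, config.mode, config.effective_min_support)
            for b in bundles
        ]
        patches = cons.realign_patches(
            patches, contigs, config.anchor_bp, config.max_overhang
        )
        counts["patches_filled"] = sum(1 for p in patches if p.fill is not None)

        stage = "graph"
        g = gr.build_graph(contig_records, patches)
        g = gr.collapse_linear(g)
        g = gr.pop_bubbles(g)
        result = gr.resolve_repeats_and_branches(g)
        counts["scaffold_paths"] = len(result.paths)
        counts["removed_haplotigs"] = len(result.removed_haplotigs)

        stage = "absorb"
        patch_by_edge = {p.edge_id: p for p in patches}
        used_edge_ids = {
            getattr(f, "edge_id", "") for path in result.paths for f in path.fills
        }
        used_patches = [
            p for p in patches if p.edge_id in used_edge_ids and p.fill is not None
        ]
        singleton_ids = {
            path.members[0][0]
            for path in result.paths
            if len(path.members) == 1 and result.repeat_insertions.get(path.members[0][0], 0) == 0
        }
        _, absorbed = cons.absorb_contained_contigs(used_patches, contigs, singleton_ids)
        respliced = [p for p in used_patches if not p.anchored and p.seq is not None]
        if respliced:
            cons.realign_patches(respliced, contigs, config.anchor_bp, config.max_overhang)
        counts["absorbed_contigs"] = len(absorbed)
        final_paths = [
            path
            for path in result.paths
            if not (len(path.members) == 1 and path.members[0][0] in absorbed)
        ]

        stage = "emit"
        layouts = _paths_to_layouts(final_paths, patch_by_edge)
        out_fa = f"{prefix}.scaffolds.fa"
        out_agp = f"{prefix}.agp"
        scaffold_lengths = write_scaffolds(layouts, contigs, out_fa, out_agp)
        out_junctions = f"{prefix}.junctions.tsv"
        write_junction_report(layouts, out_junctions)
        out_patches = f"{prefix}.patches.fa"
        emitted_patch_ids = {
            gap.patch_id
            for layout in layouts
            for gap in layout.gaps
            if gap.seq and gap.patch_id
        }
        patch_records = [
            SequenceRecord(p.edge_id, p.fill)
            for p in patches
            if p.fill and p.edge_id in emitted_patch_ids
        ]
        write_fasta(patch_records, out_patches)
        removed_ids = sorted({cid for cid, _ in result.removed_haplotigs})
        out_removed = f"{prefix}.removed_haplotigs.fa"
        write_fasta([contigs[cid] for cid in removed_ids], out_removed)
        out_absorbed = f"{prefix}.absorbed.tsv"
        with open(out_absorbed, "w") as fh:
            fh.write("contig\tlength\n")
            for cid in sorted(absorbed):
                fh.write(f"{cid}\t{contigs[cid].length}\n")
        outputs.update(
            scaffolds=out_fa,
            agp=out_agp,
            junctions=out_junctions,
            patches=out_patches,
            removed_haplotigs=out_removed,
            absorbed=out_absorbed,
        )

        stage = "accounting"
        accounting = _accounting(layouts, contigs, removed_ids, absorbed, scaffold_lengths)
        for key, val in sorted(counts.items()):
            log.info("count %s = %d", key, val)
        for key, val in sorted(accounting.items()):
            log.info("accounting %s = %d", key, val)
        if accounting["lhs"] != accounting["rhs"]:
            raise AssertionError(
                f"byte accounting mismatch: {accounting['lhs']} != {accounting['rhs']}"
            )

        return RunResult(
            layouts=layouts,
            contigs=contigs,
            patches=patches,
            removed_haplotigs=removed_ids,
            absorbed=sorted(absorbed),
            repeat_insertions={
                cid: n for cid, n in result.repeat_insertions.items() if n > 0
            },
            counts=counts,
            accounting=accounting,
            outputs=outputs,
            warnings=warnings,
        )
    except (ConfigError, StageError):
        raise
    except BaseException as exc:
        for path in outputs.values():
            if path != str(log_path) and Path(path).exists():
                os.replace(path, path + ".partial")
        raise StageError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _accounting(
    layouts: list[ScaffoldLayout],
    contigs: dict[str, SequenceRecord],
    removed_ids: list[str],
    absorbed: list[str],
    scaffold_lengths: dict[str, int],
) -> dict[str, int]:
    """Base-level conservation check.

    scaffolds + removed_haplotigs + absorbed ==
    input + duplicated_repeat_bases + fill_bases - trimmed_bases
    """
    input_bases = sum(c.length for c in contigs.values())
    scaffold_bases = sum(scaffold_lengths.values())
    removed_bases = sum(contigs[cid].length for cid in removed_ids)
    absorbed_bases = sum(contigs[cid].length for cid in absorbed)
    appearances: dict[str, int] = {}
    fill_bases = 0
    trimmed = 0
    for layout in layouts:
        for cid, _ in layout.members:
            appearances[cid] = appearances.get(cid, 0) + 1
        for gap in layout.gaps:
            fill_bases += len(gap.seq) if gap.seq is not None else gap.n_run
            trimmed += gap.left_trim + gap.right_trim
    dup_bases = sum(
        (n - 1) * contigs[cid].length for cid, n in appearances.items() if n > 1
    )
    return {
        "input_bases": input_bases,
        "scaffold_bases": scaffold_bases,
        "removed_haplotig_bases": removed_bases,
        "absorbed_bases": absorbed_bases,
        "duplicated_repeat_bases": dup_bases,
        "fill_bases": fill_bases,
        "trimmed_bases": trimmed,
        "lhs": scaffold_bases + removed_bases + absorbed_bases,
        "rhs": input_bases + dup_bases + fill_bases - trimmed,
    }
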