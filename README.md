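# gapspan

Scaffold and gap-fill an existing genome assembly using long reads
(ONT or PacBio CLR) or a second assembly of the same genome. Unlike
plain scaffolders, every spanned gap is filled with a consensus
sequence ("patch") built from the joining reads, so the output
scaffolds are gap-free wherever the evidence allows.

## How it works

1. **Align** all joining sequences to the contigs with minimap2
   (preset chosen by `-d ont|pbclr|asm`), or consume a precomputed PAF.
2. **Filter** to *proper* alignments: block length >= `--min-aln-len`
   (default 5000 bp) and, wherever the read runs past a contig end, at
   most `--max-overhang` (default 1000 bp) of the contig left
   unaligned. Overhangs tolerate local mis-assemblies at contig tips,
   which the patches later correct by trimming.
3. **Link & bundle**: a read properly aligned to two or more contigs
   creates junction links between the facing contig ends; concordant
   links are bundled, and bundles below `--min-support` (default 2 in
   read modes, 1 in `asm` mode) are dropped.
4. **Patch consensus**: each bundle's spanning read intervals are
   reduced to a consensus by template selection plus per-column
   majority vote (skipped in `asm` mode, where the supporting interval
   is used verbatim). Patches are re-anchored onto their flanking
   contigs to fix trim points; patches that fail to anchor leave an
   N-gap instead.
5. **Graph resolution**: contigs become nodes with begin/end sides,
   anchored junctions become edges. Linear chains collapse into
   super-nodes; bubbles (parallel haplotype branches) are popped
   iteratively, keeping the longest branch; repeat nodes (>= 2 edges on
   both sides) are removed, remaining ambiguous branches are broken,
   and repeats are re-inserted into the resulting linear paths with
   sequence duplication where flank evidence supports it.
6. **Emit**: scaffold FASTA, AGP v2.1, a junction report, the patch
   FASTA, removed haplotype variants, and a report of short contigs
   absorbed into patches (contigs uniquely contained in a patch at
   >95% identity over >95% of their length are spliced in and removed
   from the output).

The tool works best on input assemblies whose N90 exceeds the minimum
alignment length; a warning is printed otherwise. Lowering
`--min-aln-len` (e.g. to 2500) scaffolds more aggressively at the cost
of more potential mis-joins.

## CLI

```sh
# scaffold an assembly with ONT reads
gapspan scaffold -a assembly.fa -j reads.fq.gz -d ont -t 8 -o out/run

# reconcile with a second assembly (no consensus step)
gapspan scaffold -a assembly.fa -j other_assembly.fa -d asm -o out/run

# synthetic benchmark with known truth
gapspan simulate --length 200000 --n-contigs 15 --coverage 20 -o sim
gapspan scaffold -a sim/contigs.fa -j sim/reads.fa -d ont -o run/out
gapspan evaluate --agp run/out.agp --contigs sim/contigs.fa \
    --genome sim/genome.fa --truth sim/truth.tsv \
    --patches run/out.patches.fa -o eval.tsv
```

Exit codes: 0 success, 2 configuration error, 3 stage failure.

Outputs per run prefix: `.scaffolds.fa`, `.agp`, `.junctions.tsv`,
`.patches.fa`, `.removed_haplotigs.fa`, `.absorbed.tsv`, `.log` (all
parameters and per-stage counts), plus `.aln.paf` (cached; reruns with
identical inputs reuse it).

## Library layout

- `gapspan.io` — FASTA/FASTQ/PAF parsing, scaffold FASTA + AGP +
  junction-report emission
- `gapspan.align` — aligner invocation, best-alignment selection,
  proper-alignment classification, link extraction and bundling
- `gapspan.consensus` — patch consensus, re-anchoring,
  contained-contig absorption
- `gapspan.graph` — contig graph, chain collapsing, bubble popping,
  repeat/branch resolution; debug edge-list dump/load
- `gapspan.simdata` — synthetic genomes/assemblies/reads with truth
  tables, N50/NG50/N90, truth-based evaluation
- `gapspan.pipeline` — end-to-end orchestration and accounting
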