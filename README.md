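# backsplice

Detection of post-transcriptional exon shuffling (PTES) junctions —
the back-splice junctions that define most circular RNAs — from RNA-seq
reads, using existing transcript annotation.

## The problem

A PTES transcript contains a splice junction whose exon order is
inconsistent with the genome: the 3' end of a downstream exon (the
*donor*) is joined to the 5' start of an upstream exon or of the same
exon (the *acceptor*), e.g. exon 3 spliced to exon 1. Reads spanning
such a junction are the only direct evidence for these transcripts, and
they are easily mimicked by artifacts: template switching during cDNA
synthesis, pseudogenes, segmental duplications, and high sequence
identity between neighbouring exons. This package identifies PTES
junctions at annotated splice sites and systematically removes those
artifact classes, for anyone quantifying circRNA/PTES abundance from
bulk or single-cell RNA-seq.

## Method

Inputs: reads (FASTQ), genome (FASTA), transcript annotation (BED12).
Three phases:

1. **Discovery.** Terminal *anchors* (default 20 bp) from each read are
   placed on the spliced transcript sequences with at most one mismatch.
   A read whose anchors land on one gene, in the same orientation, but
   in inverted order (head anchor downstream of the tail anchor in
   transcript coordinates) implies a PTES junction between the two
   anchor-containing exons. Cross-gene pairs (fusion-like) and
   opposite-orientation pairs (sense–antisense template switching) are
   excluded. Each junction yields a sequence *construct*: the last 65 bp
   of the donor exon + the first 65 bp of the acceptor exon (full exon
   if shorter).
2. **Evaluation.** All reads are re-mapped end-to-end to the construct
   library, so junctions near read termini are still captured. A
   user-supplied construct FASTA can replace discovery (*guided* mode).
3. **Filtering.** Each construct-mapped read must survive:
   - *competitive filters*: removed if some genome or transcriptome
     placement has edit distance `NM_ref <= NM_construct` **and**
     perfectly aligned bases `>=` the construct placement's (this kills
     pseudogene/duplication mimics and neighbouring-exon identity);
   - *JSpan*: no mismatch or indel within `n` bases around the junction
     (`n/2` per side, `n` even, default 8);
   - *PID*: percent identity computed independently for the read
     segments on each side of the junction, both `>=` threshold
     (default 85 %).

   Reads tying across different junctions are ambiguous and discarded.
   Structures with at least one retained read are reported in BED6
   (score = supporting read count), together with read counts over the
   canonical junctions of the same genes for circular-vs-linear
   comparisons, and a per-read verdict table for filter-overlap (Venn)
   accounting.

A seeded simulator generates synthetic genomes/annotations, truth PTES
and canonical junction sets, and junction-spanning reads, and scores any
caller with sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
FDR = FP/(TP+FP).

All alignment is done by a built-in k-mer-seeded aligner emitting
SAM-semantics CIGAR/MD/NM records (the filters are defined purely on
those fields, so any external SAM-with-MD aligner satisfies the same
contract). See `docs/methods.md` for the model details and parameter
rationale.

## Worked example

```
backsplice simulate --out sim --seed 7 --n-genes 40 --n-ptes 60 \
    --n-canonical 60 --coverage 10
backsplice discover --reads sim.reads.fastq --genome sim.genome.fa \
    --annotation sim.annotation.bed --out run
backsplice score --calls run.ptes.bed --truth sim.truth.tsv
```

The simulate step writes a 40-gene genome with 60 backsplice + 60
canonical truth junctions and 1200 junction-spanning 100 bp reads. The
discover step prints a run report (abridged):

```
"total_reads": 1200,
"structures": 57,
"construct_mapped_reads": 232,
"retained_reads": 206,
"filtered_reads": {"genomic": 16, "transcriptomic": 22,
                   "jspan": 13, "pid": 25, "ambiguous": 0},
"discovery": {"ptes_candidate": 390, "canonical_order": 612,
              "multilocus": 0, "sense_antisense": 0, "unmapped": 198}
```

390 reads have inverted anchor pairs, defining 57 distinct junction
structures after filtering; the filtered reads are marginal alignments
whose junction sits too close to a read end. Scoring against truth:

```
"tp": 57, "fp": 0, "fn": 3, "tn": 60,
"sensitivity": 0.95, "specificity": 1.0, "fdr": 0.0
```

The 3 missed junctions had no read with the junction far enough from
both read ends — the expected sensitivity limit of anchor-based
discovery at finite coverage (see `docs/methods.md`).

Other subcommands: `guided` (re-evaluate reads against
`run.constructs.fa` from a previous run), `sweep` (retained-read counts
over the JSpan 4–14 × PID 60–100 grid).

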