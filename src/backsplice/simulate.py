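"""Synthetic reference, truth junction sets, junction-spanning reads,
and caller scoring.

The generator emulates a benchmark design in which junction constructs
are built by concatenating the full sequences of the two exons involved
(backsplice order for shuffled junctions, linear order for canonical
ones) and fixed-length reads are drawn with random start positions
subject to spanning the junction. Genomes are i.i.d. uniform sequence:
exon geometry, not base composition, drives detectability, and random
sequence makes anchor placements unique with overwhelming probability.

Scoring compares called genomic junction keys with truth keys exactly:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    FDR         = FP / (TP + FP)   (0 when no calls)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .reference import (
    GenomeSource,
    TranscriptModel,
    TranscriptomeIndex,
    exon_sequence,
    junction_key,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    ``coverage`` is the number of junction-spanning reads emitted per
    truth junction (``coverage_mode='construct'`` instead draws read
    starts uniformly over the whole construct, spanning or not).
    """

    n_genes: int = 160
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (120, 400)
    intron_length: tuple[int, int] = (200, 600)
    intergenic_length: tuple[int, int] = (300, 800)
    n_ptes: int = 500
    n_canonical: int = 500
    read_length: int = 100
    coverage: int = 10
    error_rate: float = 0.0
    coverage_mode: str = "spanning"  # 'spanning' | 'construct'
    chrom_name: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        if self.read_length > self.exon_length[0]:
            raise ValueError("read_length must not exceed the minimum exon length")
        if self.coverage_mode not in ("spanning", "construct"):
            raise ValueError("coverage_mode must be 'spanning' or 'construct'")


@dataclass(frozen=True)
class TruthJunction:
    kind: str  # 'ptes' | 'canonical'
    transcript_id: str
    donor_index: int
    acceptor_index: int
    key: tuple[str, str, int, int]


@dataclass
class TruthTable:
    junctions: list[TruthJunction]
    # per junction key: list of donor-side lengths of emitted reads
    reads: dict[tuple, list[int]] = field(default_factory=dict)

    def keys(self, kind: str) -> set[tuple]:
        return {j.key for j in self.junctions if j.kind == kind}


@dataclass(frozen=True)
class BenchmarkMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    no_calls: bool = False

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def fdr(self) -> float:
        return self.fp / (self.tp + self.fp) if self.tp + self.fp else 0.0


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def simulate_reference(config: SimulationConfig,
                       ) -> tuple[dict[str, str], TranscriptomeIndex]:
    """Random genome plus a non-overlapping multi-exon gene annotation.

    Deterministic under ``config.seed``: same config, byte-identical
    genome and annotation.
    """
    rng = np.random.default_rng(config.seed)
    transcripts = []
    cursor = 0
    layout: list[tuple[int, int]] = []  # all exon intervals, for length calc
    gene_records = []
    for g in range(config.n_genes):
        cursor += int(rng.integers(*config.intergenic_length, endpoint=True))
        n_exons = int(rng.integers(*config.exons_per_gene, endpoint=True))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        for i in range(n_exons):
            if i:
                cursor += int(rng.integers(*config.intron_length, endpoint=True))
            length = int(rng.integers(*config.exon_length, endpoint=True))
            exons.append((cursor, cursor + length))
            cursor += length
        gene_records.append((g, strand, exons))
        layout.extend(exons)
    genome_len = cursor + int(rng.integers(*config.intergenic_length, endpoint=True))
    sequence = _random_seq(rng, genome_len)
    genome = {config.chrom_name: sequence}
    for g, strand, exons_genomic in gene_records:
        name = f"GENE{g:04d}|TX1"
        exons = tuple(exons_genomic if strand == "+" else exons_genomic[::-1])
        transcripts.append(TranscriptModel(
            transcript_id=name, gene_id=name.split("|")[0],
            chrom=config.chrom_name, strand=strand, exons=exons))
    return genome, TranscriptomeIndex(transcripts)


def sample_truth_junctions(transcriptome: TranscriptomeIndex,
                           n_ptes: int, n_canonical: int,
                           rng: np.random.Generator) -> TruthTable:
    """Draw disjoint backsplice and canonical truth junction sets.

    Backsplice junctions are (acceptor exon i, donor exon j) pairs with
    i <= j within one transcript (i == j: single-exon circle); canonical
    junctions are consecutive pairs. Keys are unique by construction on
    non-overlapping genes; the two sets cannot collide because they use
    different splice-site boundary types.
    """
    ptes_pool = []
    canon_pool = []
    for tx in transcriptome:
        for i in range(tx.exon_count):
            for j in range(i, tx.exon_count):
                ptes_pool.append((tx.transcript_id, j, i))
            if i + 1 < tx.exon_count:
                canon_pool.append((tx.transcript_id, i, i + 1))
    if n_ptes > len(ptes_pool) or n_canonical > len(canon_pool):
        raise ValueError(
            f"junction space too small: {len(ptes_pool)} backsplice / "
            f"{len(canon_pool)} canonical pairs available")
    junctions: list[TruthJunction] = []
    seen_keys: set[tuple] = set()
    for kind, pool, n in (("ptes", ptes_pool, n_ptes),
                          ("canonical", canon_pool, n_canonical)):
        picks = rng.choice(len(pool), size=n, replace=False)
        for idx in sorted(int(p) for p in picks):
            tx_id, donor_idx, acceptor_idx = pool[idx]
            tx = transcriptome[tx_id]
            key = junction_key(tx.chrom, tx.strand, tx.exons[donor_idx],
                               tx.exons[acceptor_idx])
            if key in seen_keys:
                raise AssertionError("truth junction keys must be unique")
            seen_keys.add(key)
            junctions.append(TruthJunction(kind, tx_id, donor_idx, acceptor_idx, key))
    return TruthTable(junctions=junctions)


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[int(rng.integers(len(choices)))]])
    return arr.tobytes().decode()


def simulate_reads(truth: TruthTable, transcriptome: TranscriptomeIndex,
                   genome: GenomeSource | dict[str, str],
                   config: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   ) -> list[tuple[str, str]]:
    """Emit reads per truth junction and record per-read donor-side
    lengths in the truth table.

    Each junction's construct is the full donor exon followed by the
    full acceptor exon; a read with donor-side length ``d`` starts ``d``
    bases before the junction. In 'spanning' mode ``d`` is uniform over
    the feasible part of ``[1, read_length - 1]``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if not isinstance(genome, GenomeSource):
        genome = GenomeSource(genome)
    L = config.read_length
    reads: list[tuple[str, str]] = []
    for jn in truth.junctions:
        tx = transcriptome[jn.transcript_id]
        donor_seq = exon_sequence(genome, tx, jn.donor_index)
        acceptor_seq = exon_sequence(genome, tx, jn.acceptor_index)
        construct = donor_seq + acceptor_seq
        jo = len(donor_seq)
        d_list = truth.reads.setdefault(jn.key, [])
        for i in range(config.coverage):
            if config.coverage_mode == "spanning":
                lo = max(1, L - len(acceptor_seq))
                hi = min(L - 1, len(donor_seq))
                d = int(rng.integers(lo, hi, endpoint=True))
                start = jo - d
            else:
                start = int(rng.integers(0, len(construct) - L, endpoint=True))
                d = jo - start  # may fall outside [1, L-1]: non-spanning read
            seq = _apply_errors(construct[start:start + L], config.error_rate, rng)
            reads.append((f"sim|{jn.kind}|{jn.key[0]}:{jn.key[2]}-{jn.key[3]}:{jn.key[1]}|r{i}|d{d}",
                          seq))
            d_list.append(d)
    return reads


def score_calls(called_keys: Iterable[tuple[str, str, int, int]],
                truth: TruthTable) -> BenchmarkMetrics:
    """TP/FP/FN/TN of a called junction key set against the truth table."""
    calls = set(called_keys)
    ptes = truth.keys("ptes")
    canonical = truth.keys("canonical")
    tp = len(calls & ptes)
    fp = len(calls - ptes)
    fn = len(ptes - calls)
    tn = len(canonical - calls)
    return BenchmarkMetrics(tp=tp, fp=fp, fn=fn, tn=tn, no_calls=not calls)


def write_reference_files(genome: dict[str, str],
                          transcriptome: TranscriptomeIndex,
                          genome_path: str | Path, bed_path: str | Path) -> None:
    with open(genome_path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    with open(bed_path, "w") as fh:
        for tx in transcriptome:
            genomic = sorted(tx.exons)
            start = genomic[0][0]
            end = genomic[-1][1]
            sizes = ",".join(str(e - s) for s, e in genomic) + ","
            starts = ",".join(str(s - start) for s, _ in genomic) + ","
            fh.write("\t".join(map(str, [
                tx.chrom, start, end, tx.transcript_id, 0, tx.strand,
                start, end, 0, len(genomic), sizes, starts])) + "\n")


def write_reads_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\ttranscript_id\tdonor_index\tacceptor_index\t"
                 "chrom\tstrand\tstart\tend\tn_reads\tdonor_side_lengths\n")
        for jn in truth.junctions:
            ds = truth.reads.get(jn.key, [])
            fh.write("\t".join(map(str, [
                jn.kind, jn.transcript_id, jn.donor_index, jn.acceptor_index,
                jn.key[0], jn.key[1], jn.key[2], jn.key[3], len(ds),
                ",".join(map(str, ds))])) + "\n")


def read_truth_table(path: str | Path) -> TruthTable:
    junctions = []
    reads: dict[tuple, list[int]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            key = (f[4], f[5], int(f[6]), int(f[7]))
            junctions.append(TruthJunction(f[0], f[1], int(f[2]), int(f[3]), key))
            reads[key] = [int(x) for x in f[9].split(",") if x] if len(f) > 9 else []
    return TruthTable(junctions=junctions, reads=reads)
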