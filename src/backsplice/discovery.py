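"""Discovery phase: anchor extraction, inverted-pair classification and
putative backsplice junction inference.

Terminal anchors (default 20 bp) from each read are placed on the
spliced transcript sequences with tolerance for one mismatch. A read is
a backsplice candidate when its two anchors land on transcripts of one
gene, in the same orientation, but in inverted order relative to their
order in the read — the head anchor strictly downstream (in transcript
coordinates) of the tail anchor. Pairs landing on different genes
(gene-fusion-like) or in opposite orientations (sense-antisense
template-switching artifacts) are excluded. Anchor placements that
straddle a splice junction are discarded; the donor exon is the exon
containing the head anchor, the acceptor exon the one containing the
tail anchor.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .align import AlignmentRecord, ReferenceIndex, align_anchor
from .reference import (
    DEFAULT_SEGMENT_SIZE,
    GenomeSource,
    JunctionConstruct,
    TranscriptomeIndex,
    junction_key,
    make_construct,
    spliced_sequence,
)

DEFAULT_ANCHOR_LEN = 20

CATEGORIES = ("ptes_candidate", "canonical_order", "multilocus",
              "sense_antisense", "unmapped")


@dataclass(frozen=True)
class AnchorPair:
    read_id: str
    head_anchor: str
    tail_anchor: str


@dataclass
class PairClassification:
    category: str
    # qualifying (head placement, tail placement) pairs for candidates
    supporting_pairs: list[tuple[AlignmentRecord, AlignmentRecord]] = field(
        default_factory=list)


@dataclass
class DiscoveryStats:
    total_reads: int = 0
    too_short: int = 0
    categories: Counter = field(default_factory=Counter)

    def as_rows(self) -> list[tuple[str, int]]:
        rows = [("total_reads", self.total_reads), ("too_short", self.too_short)]
        rows += [(c, self.categories.get(c, 0)) for c in CATEGORIES]
        return rows


def extract_anchors(read_sequence: str, anchor_len: int = DEFAULT_ANCHOR_LEN) -> tuple[str, str] | None:
    """Head and tail anchors of a read; None for reads shorter than two
    anchors (skipped and counted by the caller)."""
    if anchor_len < 10:
        raise ValueError("anchor_len must be >= 10")
    if len(read_sequence) < 2 * anchor_len:
        return None
    return read_sequence[:anchor_len], read_sequence[-anchor_len:]


def _inverted(head: AlignmentRecord, tail: AlignmentRecord) -> bool:
    """Inverted-order test for a same-strand placement pair.

    For forward/forward pairs the head anchor must lie strictly
    downstream of the tail anchor in transcript coordinates. A pair
    where both anchors place on the reverse complement is the mirror
    image: it corresponds to the forward pair of the reverse-complemented
    read, whose head/tail roles are swapped, so the test flips.
    """
    if head.strand == "+":
        return head.reference_start > tail.reference_start
    return tail.reference_start > head.reference_start


def classify_pair(head_placements: Sequence[AlignmentRecord],
                  tail_placements: Sequence[AlignmentRecord],
                  transcriptome: TranscriptomeIndex) -> PairClassification:
    """Classify a read from its anchor placement lists."""
    qualifying: list[tuple[AlignmentRecord, AlignmentRecord]] = []
    qualifying_genes: set[str] = set()
    same_gene_linear = False
    same_gene_antisense = False
    any_pair = False
    for h in head_placements:
        gene_h = transcriptome.gene_of(h.reference_id)
        for t in tail_placements:
            any_pair = True
            gene_t = transcriptome.gene_of(t.reference_id)
            if gene_h != gene_t:
                continue
            if h.strand != t.strand:
                same_gene_antisense = True
                continue
            if _inverted(h, t):
                qualifying.append((h, t))
                qualifying_genes.add(gene_h)
            else:
                same_gene_linear = True
    if len(qualifying_genes) == 1:
        return PairClassification("ptes_candidate", qualifying)
    if len(qualifying_genes) > 1:
        return PairClassification("multilocus")
    if same_gene_linear:
        return PairClassification("canonical_order")
    if same_gene_antisense:
        return PairClassification("sense_antisense")
    if any_pair:
        return PairClassification("multilocus")
    return PairClassification("unmapped")


def infer_junctions(classification: PairClassification,
                    transcriptome: TranscriptomeIndex,
                    anchor_len: int = DEFAULT_ANCHOR_LEN,
                    ) -> set[tuple[str, str, str, tuple[int, int], tuple[int, int]]]:
    """Junctions implied by a candidate's qualifying placement pairs.

    Each junction is ``(gene_id, chrom, strand, donor_exon,
    acceptor_exon)`` with exons as genomic intervals. Placements not
    fully contained within a single exon are discarded; junctions are
    deduplicated by genomic coordinates.
    """
    if classification.category != "ptes_candidate":
        raise ValueError("junctions are inferred for ptes_candidate reads only")
    junctions = {}
    for h, t in classification.supporting_pairs:
        if h.strand == "-":
            # mirror pair: the reverse-complemented read's head is the
            # tail anchor's placement
            h, t = t, h
        tx_h = transcriptome[h.reference_id]
        tx_t = transcriptome[t.reference_id]
        donor_idx = tx_h.containing_exon(h.reference_start, anchor_len)
        acceptor_idx = tx_t.containing_exon(t.reference_start, anchor_len)
        if donor_idx is None or acceptor_idx is None:
            continue
        if tx_h.transcript_id == tx_t.transcript_id and donor_idx < acceptor_idx:
            continue
        donor_exon = tx_h.exons[donor_idx]
        acceptor_exon = tx_t.exons[acceptor_idx]
        key = junction_key(tx_h.chrom, tx_h.strand, donor_exon, acceptor_exon)
        junctions.setdefault(
            key, (tx_h.gene_id, tx_h.chrom, tx_h.strand, donor_exon, acceptor_exon))
    return set(junctions.values())


def build_transcriptome_index(transcriptome: TranscriptomeIndex,
                              genome: GenomeSource, k: int = 10,
                              ) -> ReferenceIndex:
    """K-mer index over spliced transcript sequences (strand-resolved)."""
    seqs = {tx.transcript_id: spliced_sequence(genome, tx) for tx in transcriptome}
    return ReferenceIndex(seqs, k=k)


def _junction_to_construct(junction, transcriptome: TranscriptomeIndex,
                           genome: GenomeSource, segment_size: int) -> JunctionConstruct:
    gene_id, chrom, strand, donor_exon, acceptor_exon = junction
    # locate a transcript of the gene carrying both exons to extract sequence
    for tx in transcriptome.genes[gene_id]:
        if donor_exon in tx.exons and acceptor_exon in tx.exons:
            return make_construct(genome, tx, tx.exons.index(donor_exon),
                                  tx.exons.index(acceptor_exon),
                                  segment_size=segment_size, kind="ptes")
    # exons from different transcripts of the gene: build from raw sequence
    from .reference import build_ptes_construct, exon_sequence, make_descriptor

    tx_d = next(tx for tx in transcriptome.genes[gene_id] if donor_exon in tx.exons)
    tx_a = next(tx for tx in transcriptome.genes[gene_id] if acceptor_exon in tx.exons)
    donor_seq = exon_sequence(genome, tx_d, tx_d.exons.index(donor_exon))
    acceptor_seq = exon_sequence(genome, tx_a, tx_a.exons.index(acceptor_exon))
    seq, offset = build_ptes_construct(donor_seq, acceptor_seq, segment_size)
    return JunctionConstruct(
        junction_id=make_descriptor(gene_id, chrom, strand, donor_exon, acceptor_exon),
        gene_id=gene_id, chrom=chrom, strand=strand,
        donor_exon=donor_exon, acceptor_exon=acceptor_exon,
        sequence=seq, junction_offset=offset, segment_size=segment_size, kind="ptes")


def discover(reads: Iterable[tuple[str, str]],
             transcriptome: TranscriptomeIndex,
             genome: GenomeSource,
             anchor_len: int = DEFAULT_ANCHOR_LEN,
             max_anchor_mismatches: int = 1,
             segment_size: int = DEFAULT_SEGMENT_SIZE,
             report_limit: int = 50,
             txome_kmer_index: ReferenceIndex | None = None,
             ) -> tuple[dict[str, JunctionConstruct], DiscoveryStats]:
    """Run the discovery phase over ``(read_id, sequence)`` pairs.

    Returns the deduplicated construct library keyed by junction
    descriptor, plus per-category read counts.
    """
    if txome_kmer_index is None:
        txome_kmer_index = build_transcriptome_index(transcriptome, genome)
    stats = DiscoveryStats()
    junctions = {}
    for read_id, seq in reads:
        stats.total_reads += 1
        anchors = extract_anchors(seq, anchor_len)
        if anchors is None:
            stats.too_short += 1
            continue
        head, tail = anchors
        placed = align_anchor({"h": head, "t": tail}, txome_kmer_index,
                              max_mismatches=max_anchor_mismatches,
                              report_limit=report_limit)
        cls = classify_pair(placed["h"], placed["t"], transcriptome)
        stats.categories[cls.category] += 1
        if cls.category != "ptes_candidate":
            continue
        for junction in infer_junctions(cls, transcriptome, anchor_len):
            key = junction_key(junction[1], junction[2], junction[3], junction[4])
            junctions.setdefault(key, junction)
    library: dict[str, JunctionConstruct] = {}
    for key in sorted(junctions):
        construct = _junction_to_construct(junctions[key], transcriptome,
                                           genome, segment_size)
        library[construct.junction_id] = construct
    return library, stats
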