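import numpy as np
import pytest

from backsplice.align import AlignmentRecord
from backsplice.discovery import (
    build_transcriptome_index,
    classify_pair,
    discover,
    extract_anchors,
    infer_junctions,
)
from backsplice.reference import (
    exon_sequence,
    junction_key,
    reverse_complement,
    spliced_sequence,
)


class TestExtractAnchors:
    def test_default_anchor_positions(self):
        read = "A" * 100
        head, tail = extract_anchors(read, 20)
        assert head == read[:20] and tail == read[80:]

    def test_abutting_anchors_processed(self):
        read = "ACGT" * 10  # 40 bp, anchors abut
        assert extract_anchors(read, 20) == (read[:20], read[20:])

    def test_short_read_skipped(self):
        assert extract_anchors("A" * 35, 20) is None

    def test_minimum_anchor_length(self):
        with pytest.raises(ValueError):
            extract_anchors("A" * 100, 9)


def _rec(ref, pos, strand="+"):
    return AlignmentRecord("a", ref, pos, strand, (("M", 20),), "20", 0, True)


class TestClassifyPair:
    def test_inverted_same_gene_is_candidate(self, toy_transcriptome):
        _, idx = toy_transcriptome
        cls = classify_pair([_rec("GENEA|TX1", 350)], [_rec("GENEA|TX1", 50)], idx)
        assert cls.category == "ptes_candidate"
        assert len(cls.supporting_pairs) == 1

    def test_cross_gene_is_multilocus(self, toy_transcriptome):
        _, idx = toy_transcriptome
        cls = classify_pair([_rec("GENEA|TX1", 350)], [_rec("GENEB|TX1", 50)], idx)
        assert cls.category == "multilocus"

    def test_opposite_orientation_is_sense_antisense(self, toy_transcriptome):
        _, idx = toy_transcriptome
        cls = classify_pair([_rec("GENEA|TX1", 350)],
                            [_rec("GENEA|TX1", 50, "-")], idx)
        assert cls.category == "sense_antisense"

    def test_linear_order_is_canonical(self, toy_transcriptome):
        _, idx = toy_transcriptome
        cls = classify_pair([_rec("GENEA|TX1", 100)], [_rec("GENEA|TX1", 400)], idx)
        assert cls.category == "canonical_order"

    def test_no_placements_is_unmapped(self, toy_transcriptome):
        _, idx = toy_transcriptome
        assert classify_pair([], [_rec("GENEA|TX1", 50)], idx).category == "unmapped"

    def test_inverted_pairs_in_two_genes_is_multilocus(self, toy_transcriptome):
        _, idx = toy_transcriptome
        cls = classify_pair([_rec("GENEA|TX1", 350), _rec("GENEB|TX1", 200)],
                            [_rec("GENEA|TX1", 50), _rec("GENEB|TX1", 20)], idx)
        assert cls.category == "multilocus"


class TestInferJunctions:
    def test_exon_contained_pair_yields_junction(self, toy_transcriptome):
        _, idx = toy_transcriptome
        tx = idx["GENEA|TX1"]
        # head inside exon 2 (offsets 300..420), tail inside exon 0 (0..120)
        cls = classify_pair([_rec("GENEA|TX1", 350)], [_rec("GENEA|TX1", 50)], idx)
        (junction,) = infer_junctions(cls, idx)
        assert junction[3] == tx.exons[2] and junction[4] == tx.exons[0]

    def test_straddling_anchor_discarded(self, toy_transcriptome):
        _, idx = toy_transcriptome
        # head anchor [110,130) crosses the exon0/exon1 boundary at 120
        cls = classify_pair([_rec("GENEA|TX1", 110)], [_rec("GENEA|TX1", 10)], idx)
        assert cls.category == "ptes_candidate"
        assert infer_junctions(cls, idx) == set()

    def test_single_exon_circle(self, toy_transcriptome):
        _, idx = toy_transcriptome
        tx = idx["GENEA|TX1"]
        cls = classify_pair([_rec("GENEA|TX1", 90)], [_rec("GENEA|TX1", 10)], idx)
        (junction,) = infer_junctions(cls, idx)
        assert junction[3] == junction[4] == tx.exons[0]


def _junction_read(genome, tx, donor_idx, acceptor_idx, d, read_len=100):
    donor = exon_sequence(genome, tx, donor_idx)
    acceptor = exon_sequence(genome, tx, acceptor_idx)
    return donor[len(donor) - d:] + acceptor[:read_len - d]


class TestDiscoverEndToEnd:
    def test_canonical_reads_yield_no_constructs(self, toy_transcriptome):
        genome, idx = toy_transcriptome
        tx = idx["GENEA|TX1"]
        seq = spliced_sequence(genome, tx)
        reads = [(f"r{i}", seq[i * 40:i * 40 + 100]) for i in range(6)]
        library, stats = discover(reads, idx, genome)
        assert library == {}
        assert stats.categories["ptes_candidate"] == 0

    def test_backsplice_read_yields_one_construct(self, toy_transcriptome):
        genome, idx = toy_transcriptome
        tx = idx["GENEA|TX1"]
        read = _junction_read(genome, tx, 2, 0, d=50)
        library, stats = discover([("r", read)], idx, genome)
        assert len(library) == 1
        (construct,) = library.values()
        assert construct.key == junction_key(tx.chrom, tx.strand,
                                             tx.exons[2], tx.exons[0])
        assert construct.junction_offset == 65

    def test_duplicate_reads_deduplicated(self, toy_transcriptome):
        genome, idx = toy_transcriptome
        tx = idx["GENEA|TX1"]
        reads = [("r1", _junction_read(genome, tx, 2, 0, d=50)),
                 ("r2", _junction_read(genome, tx, 2, 0, d=40))]
        library, _ = discover(reads, idx, genome)
        assert len(library) == 1

    def test_reverse_complement_read_detected(self, toy_transcriptome):
        genome, idx = toy_transcriptome
        tx = idx["GENEA|TX1"]
        read = reverse_complement(_junction_read(genome, tx, 2, 0, d=50))
        library, stats = discover([("r", read)], idx, genome)
        assert stats.categories["ptes_candidate"] == 1
        (construct,) = library.values()
        assert construct.key == junction_key(tx.chrom, tx.strand,
                                             tx.exons[2], tx.exons[0])

    def test_minus_strand_gene(self, toy_transcriptome):
        genome, idx = toy_transcriptome
        tx = idx["GENEB|TX1"]
        read = _junction_read(genome, tx, 1, 0, d=50)
        library, _ = discover([("r", read)], idx, genome)
        (construct,) = library.values()
        assert construct.key == junction_key(tx.chrom, "-",
                                             tx.exons[1], tx.exons[0])

    def test_detectability_window(self, toy_transcriptome):
        """Anchors discover the junction iff both lie fully within their
        exons: donor-side length d in [anchor_len, L - anchor_len]."""
        genome, idx = toy_transcriptome
        tx = idx["GENEA|TX1"]
        for d, expected in [(19, 0), (20, 1), (50, 1), (80, 1), (81, 0)]:
            read = _junction_read(genome, tx, 2, 0, d=d)
            library, _ = discover([("r", read)], idx, genome)
            assert len(library) == expected, f"d={d}"


class TestDiscoveryOracle:
    def test_matches_brute_force_enumeration(self, small_sim):
        """Candidate junction set equals a brute-force oracle that slides
        each anchor over every exon of every transcript (<=1 mismatch) and
        enumerates inverted exon pairs."""
        genome_src = small_sim["genome_src"]
        transcriptome = small_sim["transcriptome"]
        reads = small_sim["reads"][:120]
        library, _ = discover(reads, transcriptome, genome_src)
        called = {c.key for c in library.values()}

        anchor = 20
        oracle_keys = set()
        exon_seqs = {}
        for tx in transcriptome:
            for i in range(tx.exon_count):
                exon_seqs[(tx.transcript_id, i)] = np.frombuffer(
                    exon_sequence(genome_src, tx, i).encode(), dtype="S1")

        def occurrences(anchor_seq, exon_arr):
            if len(exon_arr) < anchor:
                return []
            windows = np.lib.stride_tricks.sliding_window_view(exon_arr, anchor)
            mism = (windows != anchor_seq).sum(axis=1)
            return np.nonzero(mism <= 1)[0].tolist()

        for rid, seq in reads:
            head = np.frombuffer(seq[:anchor].encode(), dtype="S1")
            tail = np.frombuffer(seq[-anchor:].encode(), dtype="S1")
            for tx in transcriptome:
                cum = tx.cumulative_offsets()
                for j in range(tx.exon_count):          # donor (head) exon
                    head_offs = occurrences(head, exon_seqs[(tx.transcript_id, j)])
                    if not head_offs:
                        continue
                    for i in range(j + 1):              # acceptor (tail) exon
                        tail_offs = occurrences(tail, exon_seqs[(tx.transcript_id, i)])
                        for oh in head_offs:
                            for ot in tail_offs:
                                if cum[j] + oh > cum[i] + ot:
                                    oracle_keys.add(junction_key(
                                        tx.chrom, tx.strand,
                                        tx.exons[j], tx.exons[i]))
        assert called == oracle_keys
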