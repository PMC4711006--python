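import numpy as np
import pytest

from backsplice.align import AlignmentRecord, profile_from_record
from backsplice.discovery import build_transcriptome_index, discover
from backsplice.filters import (
    FilterParams,
    apply_filters,
    competitive_filter,
    evaluate_reads,
    jspan_pass,
    pid_pass,
    segment_identities,
    sweep_junctional,
    venn_regions,
)
from backsplice.pipeline import build_genome_index, run_pipeline
from backsplice.reference import JunctionConstruct, exon_sequence
from backsplice.simulate import (
    SimulationConfig,
    sample_truth_junctions,
    simulate_reads,
    simulate_reference,
)


def _mapped(cigar, md, nm, start=0):
    return AlignmentRecord("q", "c", start, "+", cigar, md, nm, True)


def _profile(cigar, md, nm, qlen=100, start=0):
    return profile_from_record(_mapped(cigar, md, nm, start), "A" * qlen)


UNMAPPED = AlignmentRecord("q")


class TestFilterParams:
    def test_odd_jspan_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(jspan=7)

    def test_pid_range_enforced(self):
        with pytest.raises(ValueError):
            FilterParams(pid=101)


class TestCompetitiveFilter:
    def test_equal_quality_transcriptome_hit_fails_read(self):
        construct = _mapped((("M", 100),), "100", 0)
        profile = _profile((("M", 100),), "100", 0)
        txome = [_mapped((("M", 100),), "100", 0)]
        failed_g, failed_t = competitive_filter(construct, profile, [UNMAPPED],
                                                txome, "A" * 100)
        assert not failed_g and failed_t

    def test_worse_alternatives_pass(self):
        construct = _mapped((("M", 100),), "100", 0)
        profile = _profile((("M", 100),), "100", 0)
        genome = [_mapped((("M", 100),), "20C30G20T27", 5)]
        txome = [_mapped((("M", 100),), "20C30G20T5A20", 4)]
        assert competitive_filter(construct, profile, genome, txome,
                                  "A" * 100) == (False, False)

    def test_unmapped_alternatives_pass(self):
        construct = _mapped((("M", 100),), "98A1", 1)
        profile = _profile((("M", 100),), "98A1", 1)
        assert competitive_filter(construct, profile, [UNMAPPED], [UNMAPPED],
                                  "A" * 100) == (False, False)

    def test_equal_nm_fewer_matched_bases_passes(self):
        # clipped-style alternative: same NM but fewer perfectly aligned bases
        construct = _mapped((("M", 100),), "100", 0)
        profile = _profile((("M", 100),), "100", 0)
        short = AlignmentRecord("q", "g", 0, "+", (("S", 40), ("M", 60)),
                                "60", 0, True)
        failed_g, _ = competitive_filter(construct, profile, [short], [],
                                         "A" * 100)
        assert not failed_g


class TestJspan:
    def test_perfect_read_passes(self):
        p = _profile((("M", 100),), "100", 0)
        assert jspan_pass(p, 50, 14)

    def test_mismatch_three_bases_before_junction_fails_jspan8(self):
        p = _profile((("M", 100),), "47C52", 1)  # mismatch at construct pos 47
        assert not jspan_pass(p, 50, 8)

    def test_mismatch_ten_bases_away_passes_jspan14(self):
        p = _profile((("M", 100),), "40C59", 1)
        assert jspan_pass(p, 50, 14)

    def test_per_side_mode_doubles_window(self):
        p = _profile((("M", 100),), "40C59", 1)
        assert not jspan_pass(p, 50, 14, per_side=True)

    def test_deletion_in_window_fails(self):
        p = _profile((("M", 50), ("D", 2), ("M", 50)), "50^AC50", 2)
        assert not jspan_pass(p, 51, 8)

    def test_insertion_in_window_fails(self):
        p = _profile((("M", 50), ("I", 2), ("M", 48)), "98", 2)
        assert not jspan_pass(p, 50, 8)

    def test_read_not_spanning_junction_fails(self):
        p = _profile((("M", 100),), "100", 0, start=0)
        assert not jspan_pass(p, 150, 8)

    def test_window_clipped_at_read_end_passes(self):
        # junction 2 bases from the read end: window extends past coverage
        p = _profile((("M", 100),), "100", 0)
        assert jspan_pass(p, 98, 14)


class TestPid:
    def test_unbalanced_sides(self):
        # 50 donor-side bases all matching; 10 mismatches on the acceptor side
        md = "50" + "A" * 10 + "40"
        p = _profile((("M", 100),), md, 10)
        pid1, pid2 = segment_identities(p, 50)
        assert pid1 == 100.0 and pid2 == 80.0
        assert not pid_pass(p, 50, 85)
        assert pid_pass(p, 50, 60)

    def test_perfect_read_passes_any_threshold(self):
        p = _profile((("M", 100),), "100", 0)
        assert pid_pass(p, 50, 100)

    def test_one_sided_alignment_fails(self):
        p = _profile((("M", 100),), "100", 0)
        assert not pid_pass(p, 0, 60)

    def test_insertion_at_junction_counts_toward_acceptor(self):
        p = _profile((("M", 50), ("I", 2), ("M", 48)), "98", 2)
        pid1, pid2 = segment_identities(p, 50)
        assert pid1 == 100.0
        assert pid2 == pytest.approx(100 * 48 / 50)


class TestAmbiguity:
    def test_tie_across_junction_keys_is_ambiguous(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=130))
        c1 = JunctionConstruct("j1", "G1", "c", "+", (500, 600), (100, 200),
                               seq, 65)
        c2 = JunctionConstruct("j2", "G2", "c", "+", (900, 990), (700, 800),
                               seq, 65)
        read = seq[10:110]
        out = evaluate_reads([("r", read)], {"j1": c1, "j2": c2})
        _, _, ambiguous = out["r"]
        assert ambiguous


@pytest.fixture(scope="module")
def noisy_sim():
    """Small dataset with sequencing errors so every filter has work."""
    cfg = SimulationConfig(n_genes=12, exons_per_gene=(3, 5), n_ptes=12,
                           n_canonical=12, coverage=6, error_rate=0.03, seed=11)
    genome, transcriptome = simulate_reference(cfg)
    truth = sample_truth_junctions(transcriptome, cfg.n_ptes, cfg.n_canonical,
                                   np.random.default_rng(5))
    reads = simulate_reads(truth, transcriptome, genome, cfg,
                           np.random.default_rng(6))
    from backsplice.reference import GenomeSource

    genome_src = GenomeSource(genome)
    txome_index = build_transcriptome_index(transcriptome, genome_src)
    genome_index = build_genome_index(genome_src)
    library, _ = discover(reads, transcriptome, genome_src,
                          txome_kmer_index=txome_index)
    return {"cfg": cfg, "genome_src": genome_src, "transcriptome": transcriptome,
            "truth": truth, "reads": reads, "library": library,
            "txome_index": txome_index, "genome_index": genome_index}


class TestApplyFilters:
    def test_all_flags_evaluated_for_every_read(self, noisy_sim):
        _, verdicts = apply_filters(noisy_sim["reads"], noisy_sim["library"],
                                    noisy_sim["genome_index"],
                                    noisy_sim["txome_index"])
        assert verdicts, "no construct-mapped reads"
        for v in verdicts:
            # flags are booleans, set or not, for every mapped read
            assert v.nm_construct is not None

    def test_venn_accounting_conserves_reads(self, noisy_sim):
        _, verdicts = apply_filters(noisy_sim["reads"], noisy_sim["library"],
                                    noisy_sim["genome_index"],
                                    noisy_sim["txome_index"])
        failed_any = sum(1 for v in verdicts
                         if v.failed_genomic or v.failed_transcriptomic
                         or v.failed_jspan or v.failed_pid)
        regions = venn_regions(verdicts)
        assert len(regions) <= 7
        assert sum(regions.values()) == failed_any

    def test_structures_require_retained_reads(self, noisy_sim):
        calls, verdicts = apply_filters(noisy_sim["reads"], noisy_sim["library"],
                                        noisy_sim["genome_index"],
                                        noisy_sim["txome_index"])
        retained_constructs = {v.construct_id for v in verdicts if v.retained}
        assert {c.construct.junction_id for c in calls} == retained_constructs
        assert all(c.read_count >= 1 for c in calls)

    def test_monotone_in_pid_and_jspan(self, noisy_sim):
        jspans = (4, 6, 8, 10, 12, 14)
        pids = (60.0, 65.0, 70.0, 75.0, 80.0, 85.0, 90.0, 95.0, 100.0)
        rows = sweep_junctional(noisy_sim["reads"], noisy_sim["library"],
                                noisy_sim["genome_index"],
                                noisy_sim["txome_index"], jspans, pids)
        assert len(rows) == 54
        table = {(r["jspan"], r["pid"]): r["retained_reads"] for r in rows}
        for jspan in jspans:
            for lo, hi in zip(pids, pids[1:]):
                assert table[(jspan, hi)] <= table[(jspan, lo)]
        for pid in pids:
            for lo, hi in zip(jspans, jspans[1:]):
                assert table[(hi, pid)] <= table[(lo, pid)]

    def test_guided_equals_unguided(self, noisy_sim):
        unguided = run_pipeline(noisy_sim["reads"], noisy_sim["transcriptome"],
                                noisy_sim["genome_src"],
                                genome_index=noisy_sim["genome_index"],
                                txome_index=noisy_sim["txome_index"])
        guided = run_pipeline(noisy_sim["reads"], noisy_sim["transcriptome"],
                              noisy_sim["genome_src"],
                              constructs=unguided.library,
                              genome_index=noisy_sim["genome_index"],
                              txome_index=noisy_sim["txome_index"])
        assert {c.key: c.read_count for c in unguided.calls} == \
               {c.key: c.read_count for c in guided.calls}

    def test_canonical_only_input_yields_no_calls(self):
        cfg = SimulationConfig(n_genes=10, exons_per_gene=(3, 5), n_ptes=0,
                               n_canonical=20, coverage=8, seed=21)
        genome, transcriptome = simulate_reference(cfg)
        truth = sample_truth_junctions(transcriptome, 0, 20,
                                       np.random.default_rng(9))
        reads = simulate_reads(truth, transcriptome, genome, cfg,
                               np.random.default_rng(10))
        result = run_pipeline(reads, transcriptome, genome)
        assert result.calls == []
        assert result.stats.categories["ptes_candidate"] == 0
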