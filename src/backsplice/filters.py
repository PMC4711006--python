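"""Evaluation and filtering phases.

Every read is re-mapped end-to-end to the junction construct library
(discovered, or user-supplied in guided mode). Construct-mapped reads
then face three filter families, all computed for every read so that
per-filter overlap (Venn) accounting stays possible:

* competitive (genomic / transcriptomic): the read is removed when some
  placement on the genome or on the spliced transcriptome is as good or
  better than its construct placement — edit distance (NM) no larger
  *and* perfectly aligned bases no fewer.
* JSpan: no mismatches or indels within a window of ``jspan`` bases
  centred on the junction (``jspan/2`` per side; ``jspan`` must be
  even). Targets template-switching artifacts, whose junctions sit in
  short regions of imperfect homology.
* PID: percent identity computed independently for the read segments on
  either side of the junction; both must reach the threshold.

Reads tying their best alignment across constructs with different
junction keys are ambiguous and support nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import (
    AlignConfig,
    AlignmentRecord,
    BaseProfile,
    ReferenceIndex,
    align_full,
    profile_from_record,
)
from .reference import DEFAULT_SEGMENT_SIZE, JunctionConstruct


@dataclass(frozen=True)
class FilterParams:
    """User-adjustable pipeline parameters.

    ``jspan`` is the total width of the perfect-match window centred on
    the junction (even; default 8). With ``jspan_per_side=True`` the
    window is ``jspan`` bases on *each* side instead. ``pid`` is the
    per-segment percent identity threshold (default 85).
    """

    jspan: int = 8
    pid: float = 85.0
    anchor_len: int = 20
    segment_size: int = DEFAULT_SEGMENT_SIZE
    max_anchor_mismatches: int = 1
    jspan_per_side: bool = False

    def __post_init__(self):
        if self.jspan < 0 or self.jspan % 2 != 0:
            raise ValueError("jspan must be an even integer >= 0")
        if not 0 <= self.pid <= 100:
            raise ValueError("pid must be within [0, 100]")


@dataclass
class FilterVerdict:
    read_id: str
    construct_id: str | None
    failed_genomic: bool = False
    failed_transcriptomic: bool = False
    failed_jspan: bool = False
    failed_pid: bool = False
    ambiguous: bool = False
    nm_construct: int | None = None
    nm_genome: int | None = None
    nm_transcriptome: int | None = None
    pid_donor: float | None = None
    pid_acceptor: float | None = None

    @property
    def retained(self) -> bool:
        return not (self.failed_genomic or self.failed_transcriptomic
                    or self.failed_jspan or self.failed_pid or self.ambiguous)


@dataclass
class StructureCall:
    construct: JunctionConstruct
    read_count: int
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def key(self):
        return self.construct.key


@dataclass
class ReadEvaluation:
    """Parameter-independent per-read evaluation state (alignment and
    competitive comparison); junctional flags are derived from it for
    any (jspan, pid) combination, which is what sweep mode exploits."""

    read_id: str
    sequence: str
    record: AlignmentRecord
    construct: JunctionConstruct
    profile: BaseProfile
    failed_genomic: bool
    failed_transcriptomic: bool
    nm_genome: int | None
    nm_transcriptome: int | None
    ambiguous: bool = False


def evaluate_reads(reads: Iterable[tuple[str, str]],
                   construct_library: Mapping[str, JunctionConstruct],
                   align_config: AlignConfig = AlignConfig(),
                   kmer: int = 10,
                   ) -> dict[str, tuple[AlignmentRecord | None, JunctionConstruct | None, bool]]:
    """Best construct placement per read.

    Returns ``read_id -> (record, construct, ambiguous)``; ``record`` is
    None for unmapped reads, and ``ambiguous`` marks reads tying across
    constructs with different junction keys.
    """
    reads = list(reads)
    if not construct_library:
        import warnings

        warnings.warn("empty construct library: no reads can be evaluated")
        return {rid: (None, None, False) for rid, _ in reads}
    k = min(kmer, min(len(c.sequence) for c in construct_library.values()))
    index = ReferenceIndex({cid: c.sequence for cid, c in construct_library.items()}, k=k)
    placements = align_full(reads, index, align_config)
    out = {}
    for rid, _seq in reads:
        records = [r for r in placements[rid] if r.mapped]
        if not records:
            out[rid] = (None, None, False)
            continue
        keys = {construct_library[r.reference_id].key for r in records}
        best = records[0]
        out[rid] = (best, construct_library[best.reference_id], len(keys) > 1)
    return out


def _best_quality(records: Sequence[AlignmentRecord], sequence: str,
                  ) -> tuple[int, int] | None:
    """(nm, matched_bases) of the strongest placement, or None if unmapped."""
    best = None
    for rec in records:
        if not rec.mapped:
            continue
        matched = profile_from_record(rec, sequence).matched_bases
        cand = (rec.nm, matched)
        if best is None or cand[0] < best[0] or (cand[0] == best[0] and cand[1] > best[1]):
            best = cand
    return best


def competitive_filter(construct_record: AlignmentRecord,
                       construct_profile: BaseProfile,
                       genome_records: Sequence[AlignmentRecord],
                       transcriptome_records: Sequence[AlignmentRecord],
                       sequence: str) -> tuple[bool, bool]:
    """Genomic/transcriptomic competitive verdicts for one read.

    A reference placement wins when its NM is no larger *and* its count
    of perfectly aligned bases is no smaller than the construct
    placement's.
    """
    nm_c = construct_record.nm
    matched_c = construct_profile.matched_bases

    def beaten(records: Sequence[AlignmentRecord]) -> bool:
        for rec in records:
            if not rec.mapped:
                continue
            if rec.nm > nm_c:
                continue
            if profile_from_record(rec, sequence).matched_bases >= matched_c:
                return True
        return False

    return beaten(genome_records), beaten(transcriptome_records)


def _spans_junction(profile: BaseProfile, junction_offset: int) -> bool:
    has_left = has_right = False
    for state, pos in zip(profile.states, profile.ref_pos):
        if state not in ("match", "mismatch"):
            continue
        if pos < junction_offset:
            has_left = True
        else:
            has_right = True
        if has_left and has_right:
            return True
    return False


def jspan_pass(profile: BaseProfile, junction_offset: int, jspan: int,
               per_side: bool = False) -> bool:
    """Perfect-alignment window around the junction.

    The window covers construct positions ``[junction_offset - n,
    junction_offset + n)`` with ``n = jspan/2`` (or ``n = jspan`` with
    ``per_side``). Fails when the read does not span the junction, or
    when any mismatch, insertion anchor, or deleted reference base falls
    inside the window.
    """
    if not _spans_junction(profile, junction_offset):
        return False
    n = jspan if per_side else jspan // 2
    lo, hi = junction_offset - n, junction_offset + n
    for state, pos in zip(profile.states, profile.ref_pos):
        if state == "mismatch" and lo <= pos < hi:
            return False
        if state == "insertion" and lo <= pos < hi:
            return False
    for _qpos, ref_start, length in profile.deletions:
        if ref_start < hi and ref_start + length > lo:
            return False
    return True


def segment_identities(profile: BaseProfile, junction_offset: int,
                       ) -> tuple[float, float] | None:
    """Percent identity of the donor-side and acceptor-side read segments.

    Aligned bases (match, mismatch, insertion) are assigned to a side by
    construct position; insertions anchored exactly at the junction count
    toward the acceptor side. None when either side has no aligned base.
    """
    aligned = [0, 0]
    matched = [0, 0]
    for state, pos in zip(profile.states, profile.ref_pos):
        if state == "clipped":
            continue
        side = 0 if pos < junction_offset else 1
        aligned[side] += 1
        if state == "match":
            matched[side] += 1
    if aligned[0] == 0 or aligned[1] == 0:
        return None
    return (100.0 * matched[0] / aligned[0], 100.0 * matched[1] / aligned[1])


def pid_pass(profile: BaseProfile, junction_offset: int, pid: float) -> bool:
    pids = segment_identities(profile, junction_offset)
    if pids is None:
        return False
    return pids[0] >= pid and pids[1] >= pid


def _evaluate_all(reads: Sequence[tuple[str, str]],
                  construct_library: Mapping[str, JunctionConstruct],
                  genome_index: ReferenceIndex,
                  transcriptome_index: ReferenceIndex,
                  align_config: AlignConfig) -> list[ReadEvaluation]:
    evaluated = evaluate_reads(reads, construct_library, align_config)
    seq_of = dict(reads)
    evaluations = []
    for rid, _ in reads:
        record, construct, ambiguous = evaluated[rid]
        if record is None:
            continue
        sequence = seq_of[rid]
        profile = profile_from_record(record, sequence)
        genome_recs = align_full([(rid, sequence)], genome_index, align_config)[rid]
        txome_recs = align_full([(rid, sequence)], transcriptome_index, align_config)[rid]
        failed_g, failed_t = competitive_filter(record, profile, genome_recs,
                                                txome_recs, sequence)
        bg = _best_quality(genome_recs, sequence)
        bt = _best_quality(txome_recs, sequence)
        evaluations.append(ReadEvaluation(
            read_id=rid, sequence=sequence, record=record, construct=construct,
            profile=profile, failed_genomic=failed_g, failed_transcriptomic=failed_t,
            nm_genome=bg[0] if bg else None, nm_transcriptome=bt[0] if bt else None,
            ambiguous=ambiguous))
    return evaluations


def _verdict(ev: ReadEvaluation, params: FilterParams) -> FilterVerdict:
    jo = ev.construct.junction_offset
    pids = segment_identities(ev.profile, jo)
    return FilterVerdict(
        read_id=ev.read_id,
        construct_id=ev.construct.junction_id,
        failed_genomic=ev.failed_genomic,
        failed_transcriptomic=ev.failed_transcriptomic,
        failed_jspan=not jspan_pass(ev.profile, jo, params.jspan, params.jspan_per_side),
        failed_pid=not pid_pass(ev.profile, jo, params.pid),
        ambiguous=ev.ambiguous,
        nm_construct=ev.record.nm,
        nm_genome=ev.nm_genome,
        nm_transcriptome=ev.nm_transcriptome,
        pid_donor=pids[0] if pids else None,
        pid_acceptor=pids[1] if pids else None,
    )


def _calls_from_verdicts(verdicts: Sequence[FilterVerdict],
                         construct_library: Mapping[str, JunctionConstruct],
                         ) -> list[StructureCall]:
    support: dict[str, int] = {}
    excluded: dict[str, dict[str, int]] = {}
    for v in verdicts:
        if v.construct_id is None:
            continue
        tallies = excluded.setdefault(v.construct_id, {
            "genomic": 0, "transcriptomic": 0, "jspan": 0, "pid": 0, "ambiguous": 0})
        if v.retained:
            support[v.construct_id] = support.get(v.construct_id, 0) + 1
        for flag, name in ((v.failed_genomic, "genomic"),
                           (v.failed_transcriptomic, "transcriptomic"),
                           (v.failed_jspan, "jspan"), (v.failed_pid, "pid"),
                           (v.ambiguous, "ambiguous")):
            if flag:
                tallies[name] += 1
    calls = [StructureCall(construct=construct_library[cid], read_count=n,
                           excluded=excluded[cid])
             for cid, n in support.items() if n >= 1]
    calls.sort(key=lambda c: c.key)
    return calls


def apply_filters(reads: Sequence[tuple[str, str]],
                  construct_library: Mapping[str, JunctionConstruct],
                  genome_index: ReferenceIndex,
                  transcriptome_index: ReferenceIndex,
                  params: FilterParams = FilterParams(),
                  align_config: AlignConfig = AlignConfig(),
                  ) -> tuple[list[StructureCall], list[FilterVerdict]]:
    """Full evaluation + filtering: structure calls and per-read verdicts."""
    evaluations = _evaluate_all(list(reads), construct_library, genome_index,
                                transcriptome_index, align_config)
    verdicts = [_verdict(ev, params) for ev in evaluations]
    return _calls_from_verdicts(verdicts, construct_library), verdicts


def sweep_junctional(reads: Sequence[tuple[str, str]],
                     construct_library: Mapping[str, JunctionConstruct],
                     genome_index: ReferenceIndex,
                     transcriptome_index: ReferenceIndex,
                     jspans: Sequence[int],
                     pids: Sequence[float],
                     base_params: FilterParams = FilterParams(),
                     align_config: AlignConfig = AlignConfig(),
                     ) -> list[dict]:
    """Retained-read / structure counts over a (jspan, pid) grid.

    Alignments and competitive verdicts are computed once; only the
    junctional thresholds vary across the grid.
    """
    evaluations = _evaluate_all(list(reads), construct_library, genome_index,
                                transcriptome_index, align_config)
    rows = []
    for jspan in jspans:
        for pid in pids:
            params = FilterParams(jspan=jspan, pid=pid,
                                  anchor_len=base_params.anchor_len,
                                  segment_size=base_params.segment_size,
                                  max_anchor_mismatches=base_params.max_anchor_mismatches,
                                  jspan_per_side=base_params.jspan_per_side)
            verdicts = [_verdict(ev, params) for ev in evaluations]
            calls = _calls_from_verdicts(verdicts, construct_library)
            rows.append({
                "jspan": jspan, "pid": pid,
                "retained_reads": sum(1 for v in verdicts if v.retained),
                "structures": len(calls),
            })
    return rows


VENN_FAMILIES = ("genomic", "transcriptomic", "junctional")


def venn_regions(verdicts: Iterable[FilterVerdict]) -> dict[frozenset, int]:
    """Disjoint filter-overlap regions over construct-mapped reads that
    failed at least one filter family (junctional = JSpan or PID)."""
    regions: dict[frozenset, int] = {}
    for v in verdicts:
        families = set()
        if v.failed_genomic:
            families.add("genomic")
        if v.failed_transcriptomic:
            families.add("transcriptomic")
        if v.failed_jspan or v.failed_pid:
            families.add("junctional")
        if families:
            key = frozenset(families)
            regions[key] = regions.get(key, 0) + 1
    return regions
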