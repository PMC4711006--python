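"""Short-read alignment with SAM-style CIGAR/MD/NM semantics.

Two modes back the pipeline:

* ``align_anchor`` — end-to-end, ungapped placement of short terminal
  anchors against transcript sequences, tolerating a configurable number
  of mismatches (default 1), reporting all placements.
* ``align_full`` — end-to-end (query-global) placement of whole reads
  against a reference set; gapped alignments are found by k-mer seeding
  plus edit-distance verification (edlib) in a window around each seed
  diagonal, and reads whose best placement exceeds an edit-distance
  ceiling are reported unmapped.

All downstream filters consume only the record's CIGAR, MD and NM, so
records produced by an external SAM-emitting aligner satisfy the same
contract as long as MD is present.

Seeding is pigeonhole-complete: non-overlapping k-mer tiles across the
query guarantee an exact seed whenever the number of edits is smaller
than the number of tiles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .reference import reverse_complement

CigarOp = tuple[str, int]

_MD_TOKEN = re.compile(r"(\d+)|\^([A-Za-z]+)|([A-Za-z])")


class AlignmentIntegrityError(ValueError):
    """CIGAR/MD/NM of a record are mutually inconsistent."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One query-to-reference placement (or an explicit unmapped record)."""

    query_id: str
    reference_id: str | None = None
    reference_start: int = -1
    strand: str = "+"
    cigar: tuple[CigarOp, ...] = ()
    md: str | None = None
    nm: int = -1
    mapped: bool = False
    score: int = 0  # affine score (lower is better); tie-break only

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    @property
    def reference_end(self) -> int:
        return self.reference_start + sum(n for op, n in self.cigar if op in "MD")

    def validate(self, query_sequence: str | None = None) -> None:
        if not self.mapped:
            return
        if query_sequence is not None and self.query_length != len(query_sequence):
            raise AlignmentIntegrityError(
                f"{self.query_id}: CIGAR consumes {self.query_length} query bases, "
                f"query is {len(query_sequence)}")
        profile_from_record(self, "N" * self.query_length)


@dataclass
class BaseProfile:
    """Per-query-base alignment states derived from CIGAR + MD.

    ``states[i]`` is one of ``match``, ``mismatch``, ``insertion``,
    ``clipped`` for query position ``i``. ``ref_pos[i]`` is the reference
    coordinate the base is aligned to (for insertions, the coordinate of
    the next aligned reference base, which anchors the insertion);
    ``None`` for clipped bases. ``deletions`` holds ``(query_pos,
    ref_start, length)`` for each deletion, anchored before query
    position ``query_pos``.
    """

    states: list[str]
    ref_pos: list[int | None]
    deletions: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def matched_bases(self) -> int:
        return self.states.count("match")

    def __len__(self) -> int:
        return len(self.states)


def _md_tokens(md: str):
    pos = 0
    for m in _MD_TOKEN.finditer(md):
        if m.start() != pos:
            raise AlignmentIntegrityError(f"malformed MD string {md!r}")
        pos = m.end()
        if m.group(1) is not None:
            yield ("match", int(m.group(1)))
        elif m.group(2) is not None:
            yield ("del", m.group(2))
        else:
            yield ("mismatch", m.group(3))
    if pos != len(md):
        raise AlignmentIntegrityError(f"malformed MD string {md!r}")


def profile_from_record(record: AlignmentRecord, query_sequence: str) -> BaseProfile:
    """Expand a mapped record's CIGAR + MD into per-base states."""
    if not record.mapped:
        raise ValueError(f"{record.query_id}: cannot profile an unmapped record")
    if record.md is None:
        raise AlignmentIntegrityError(f"{record.query_id}: record lacks an MD string")

    tokens = list(_md_tokens(record.md))
    ti = 0
    pending_match = 0  # remaining bases of current MD match run

    def next_match_run() -> int:
        nonlocal ti, pending_match
        while pending_match == 0 and ti < len(tokens):
            kind, val = tokens[ti]
            if kind == "match":
                pending_match = val
                ti += 1
                if pending_match == 0:
                    continue
            else:
                break
        return pending_match

    states: list[str] = []
    ref_pos: list[int | None] = []
    deletions: list[tuple[int, int, int]] = []
    qpos = 0
    rpos = record.reference_start
    mismatches = 0

    for op, length in record.cigar:
        if op == "S":
            states.extend(["clipped"] * length)
            ref_pos.extend([None] * length)
            qpos += length
        elif op == "M":
            remaining = length
            while remaining:
                if next_match_run() > 0:
                    take = min(pending_match, remaining)
                    states.extend(["match"] * take)
                    ref_pos.extend(range(rpos, rpos + take))
                    pending_match -= take
                    remaining -= take
                    qpos += take
                    rpos += take
                else:
                    if ti >= len(tokens) or tokens[ti][0] != "mismatch":
                        raise AlignmentIntegrityError(
                            f"{record.query_id}: MD exhausted inside CIGAR M run")
                    ti += 1
                    states.append("mismatch")
                    ref_pos.append(rpos)
                    mismatches += 1
                    remaining -= 1
                    qpos += 1
                    rpos += 1
        elif op == "I":
            states.extend(["insertion"] * length)
            ref_pos.extend([rpos] * length)
            qpos += length
        elif op == "D":
            if next_match_run() > 0 or ti >= len(tokens) or tokens[ti][0] != "del":
                raise AlignmentIntegrityError(
                    f"{record.query_id}: CIGAR D without matching MD deletion")
            if len(tokens[ti][1]) != length:
                raise AlignmentIntegrityError(
                    f"{record.query_id}: MD deletion length mismatch")
            ti += 1
            deletions.append((qpos, rpos, length))
            rpos += length
        else:
            raise AlignmentIntegrityError(f"{record.query_id}: unsupported CIGAR op {op}")

    if next_match_run() > 0 or ti < len(tokens):
        raise AlignmentIntegrityError(f"{record.query_id}: MD longer than CIGAR")
    if qpos != len(query_sequence):
        raise AlignmentIntegrityError(
            f"{record.query_id}: CIGAR consumes {qpos} bases, query is {len(query_sequence)}")
    implied_nm = mismatches + sum(n for op, n in record.cigar if op == "I") \
        + sum(n for op, n in record.cigar if op == "D")
    if record.nm >= 0 and implied_nm != record.nm:
        raise AlignmentIntegrityError(
            f"{record.query_id}: NM {record.nm} != {implied_nm} implied by MD/CIGAR")
    return BaseProfile(states=states, ref_pos=ref_pos, deletions=deletions)


def _md_from_pairs(pairs: Iterable[tuple[str, str | None, str | None]]) -> str:
    """MD string from (op, query_base, ref_base) walk; op in {M,I,D}."""
    out: list[str] = []
    run = 0
    in_deletion = False
    for op, qb, rb in pairs:
        if op == "M":
            if qb == rb:
                run += 1
            else:
                out.append(str(run))
                out.append(rb)
                run = 0
            in_deletion = False
        elif op == "D":
            if in_deletion:
                out[-1] += rb
            else:
                out.append(str(run))
                out.append("^" + rb)
                run = 0
                in_deletion = True
        else:  # insertions are silent in MD
            in_deletion = False
    out.append(str(run))
    return "".join(out)


def _ungapped_record(query_id: str, query: str, ref_id: str, ref: str,
                     ref_start: int, strand: str,
                     mismatch_cost: int) -> AlignmentRecord | None:
    window = ref[ref_start:ref_start + len(query)]
    if len(window) != len(query):
        return None
    nm = sum(1 for a, b in zip(query, window) if a != b)
    md = _md_from_pairs(("M", a, b) for a, b in zip(query, window))
    return AlignmentRecord(
        query_id=query_id, reference_id=ref_id, reference_start=ref_start,
        strand=strand, cigar=(("M", len(query)),), md=md, nm=nm,
        mapped=True, score=nm * mismatch_cost)


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


class ReferenceIndex:
    """Exact k-mer lookup table over a set of reference sequences."""

    def __init__(self, references: Mapping[str, str], k: int = 10):
        self.references: dict[str, str] = {rid: seq.upper()
                                           for rid, seq in references.items()}
        if self.references:
            shortest = min(len(s) for s in self.references.values())
            if k > shortest:
                raise ValueError(
                    f"index k={k} exceeds shortest reference length {shortest}")
        self.k = k
        table: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in self.references.items():
            for i in range(len(seq) - k + 1):
                table.setdefault(seq[i:i + k], []).append((rid, i))
        self._table = table

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._table.get(kmer, ())

    def __contains__(self, rid: str) -> bool:
        return rid in self.references


@dataclass(frozen=True)
class AlignConfig:
    """Scoring and search parameters for full-read alignment.

    ``edit_ceiling_frac``: a read whose best placement needs more than
    this fraction of its length in edits is reported unmapped.
    The affine penalties order equal-NM placements only.
    """

    mismatch: int = 6
    gap_open: int = 5
    gap_extend: int = 3
    edit_ceiling_frac: float = 0.2
    window_pad: int = 8
    search_rc: bool = True


def _affine_score(cigar: Sequence[CigarOp], nm: int, cfg: AlignConfig) -> int:
    gap_bases = sum(n for op, n in cigar if op in "ID")
    gap_runs = sum(1 for op, n in cigar if op in "ID")
    mismatches = nm - gap_bases
    return mismatches * cfg.mismatch + gap_runs * cfg.gap_open + gap_bases * cfg.gap_extend


def _edlib_record(query_id: str, query: str, ref_id: str, ref: str,
                  window_start: int, window_end: int, strand: str,
                  ceiling: int, cfg: AlignConfig) -> AlignmentRecord | None:
    window = ref[window_start:window_end]
    res = edlib.align(query, window, mode="HW", task="path", k=ceiling)
    if res["editDistance"] < 0:
        return None
    loc_start, loc_end = res["locations"][0]
    cigar_ext = re.findall(r"(\d+)([=XIDM])", res["cigar"])
    ops: list[CigarOp] = []
    pairs: list[tuple[str, str | None, str | None]] = []
    qpos, rpos = 0, window_start + loc_start
    for n_str, op in cigar_ext:
        n = int(n_str)
        if op in "=XM":
            sam_op = "M"
            for i in range(n):
                pairs.append(("M", query[qpos + i], ref[rpos + i]))
            qpos += n
            rpos += n
        elif op == "I":
            sam_op = "I"
            qpos += n
        else:
            sam_op = "D"
            for i in range(n):
                pairs.append(("D", None, ref[rpos + i]))
            rpos += n
        if ops and ops[-1][0] == sam_op:
            ops[-1] = (sam_op, ops[-1][1] + n)
        else:
            ops.append((sam_op, n))
    # End-to-end contract: terminal query bases must align to reference
    # bases. A path starting or ending in a gap is a reference-boundary
    # overhang (the window cannot extend), not an end-to-end placement.
    if ops[0][0] in "ID" or ops[-1][0] in "ID":
        return None
    md = _md_from_pairs(pairs)
    nm = res["editDistance"]
    return AlignmentRecord(
        query_id=query_id, reference_id=ref_id,
        reference_start=window_start + loc_start, strand=strand,
        cigar=tuple(ops), md=md, nm=nm, mapped=True,
        score=_affine_score(ops, nm, cfg))


def align_anchor(queries: Mapping[str, str] | Iterable[tuple[str, str]],
                 index: ReferenceIndex,
                 max_mismatches: int = 1,
                 report_limit: int = 50,
                 search_rc: bool = True) -> dict[str, list[AlignmentRecord]]:
    """End-to-end ungapped placement of anchors, all hits reported.

    Reverse-complement placements are returned with ``strand='-'`` so
    callers can detect sense-antisense anchor pairs.
    """
    if isinstance(queries, Mapping):
        items = queries.items()
    else:
        items = queries
    k = index.k
    results: dict[str, list[AlignmentRecord]] = {}
    for qid, seq in items:
        seq = seq.upper()
        alen = len(seq)
        n_seg = max_mismatches + 1
        seg = alen // n_seg
        if seg < k:
            raise ValueError(
                f"anchor length {alen} too short for {max_mismatches} mismatches "
                f"with index k={k}")
        hits: list[AlignmentRecord] = []
        orientations = [("+", seq)]
        if search_rc:
            orientations.append(("-", reverse_complement(seq)))
        for strand, oseq in orientations:
            seen: set[tuple[str, int]] = set()
            for s in range(n_seg):
                off = s * seg
                for rid, pos in index.lookup(oseq[off:off + k]):
                    rs = pos - off
                    ref = index.references[rid]
                    if rs < 0 or rs + alen > len(ref) or (rid, rs) in seen:
                        continue
                    seen.add((rid, rs))
                    rec = _ungapped_record(qid, oseq, rid, ref, rs, strand, 1)
                    if rec is not None and rec.nm <= max_mismatches:
                        hits.append(rec)
        hits.sort(key=lambda r: (r.reference_id, r.reference_start, r.strand))
        results[qid] = hits[:report_limit]
    return results


def align_full(queries: Mapping[str, str] | Iterable[tuple[str, str]],
               index: ReferenceIndex,
               config: AlignConfig = AlignConfig()) -> dict[str, list[AlignmentRecord]]:
    """Best end-to-end placement(s) of full reads against the reference set.

    All placements tying the best NM (affine score as secondary key) are
    returned, deterministically ordered by (reference, position, strand).
    Queries whose best placement exceeds the edit ceiling are returned
    as a single unmapped record.
    """
    if isinstance(queries, Mapping):
        items = queries.items()
    else:
        items = queries
    k = index.k
    results: dict[str, list[AlignmentRecord]] = {}
    for qid, raw in items:
        query = raw.upper()
        qlen = len(query)
        ceiling = int(qlen * config.edit_ceiling_frac)
        offsets = list(range(0, max(qlen - k, 0) + 1, k))
        if offsets and offsets[-1] != qlen - k:
            offsets.append(qlen - k)
        orientations = [("+", query)]
        if config.search_rc:
            orientations.append(("-", reverse_complement(query)))
        records: dict[tuple, AlignmentRecord] = {}
        for strand, oseq in orientations:
            diagonals: set[tuple[str, int]] = set()
            for off in offsets:
                for rid, pos in index.lookup(oseq[off:off + k]):
                    diagonals.add((rid, pos - off))
            for rid, rs in sorted(diagonals):
                ref = index.references[rid]
                best: AlignmentRecord | None = None
                if 0 <= rs and rs + qlen <= len(ref):
                    best = _ungapped_record(qid, oseq, rid, ref, rs, strand,
                                            config.mismatch)
                if best is None or best.nm > 1:
                    ws = max(0, rs - config.window_pad)
                    we = min(len(ref), rs + qlen + config.window_pad)
                    gapped = _edlib_record(qid, oseq, rid, ref, ws, we, strand,
                                           ceiling, config) \
                        if we - ws >= qlen - ceiling else None
                    if gapped is not None and (best is None or
                                               (gapped.nm, gapped.score) <
                                               (best.nm, best.score)):
                        best = gapped
                if best is None or best.nm > ceiling:
                    continue
                key = (rid, best.reference_start, strand)
                prev = records.get(key)
                if prev is None or (best.nm, best.score) < (prev.nm, prev.score):
                    records[key] = best
        if not records:
            results[qid] = [AlignmentRecord(query_id=qid)]
            continue
        best_key = min((r.nm, r.score) for r in records.values())
        ties = [r for r in records.values() if (r.nm, r.score) == best_key]
        ties.sort(key=lambda r: (r.reference_id, r.reference_start, r.strand))
        results[qid] = ties
    return results
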