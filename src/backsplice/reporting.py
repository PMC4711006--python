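"""Output writers: backsplice structure BED and canonical-junction counts.

The structure BED (BED6) spans from the acceptor exon's 5' splice site
to the donor exon's 3' splice site; the name column is the junction
descriptor ``gene|chrom|strand|start|end`` and the score column the raw
count of retained supporting reads. Canonical-junction counts are
reported for every transcript of each gene with at least one reported
backsplice structure, giving linear-junction read counts directly
comparable to the backsplice counts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .align import AlignConfig, ReferenceIndex, align_full, profile_from_record
from .filters import FilterParams, FilterVerdict, StructureCall, jspan_pass, pid_pass
from .reference import (
    GenomeSource,
    JunctionConstruct,
    TranscriptomeIndex,
    junction_key,
    junction_sites,
    make_construct,
)


def _header_lines(params: FilterParams | None, extra: Mapping[str, object] | None) -> list[str]:
    lines = []
    if params is not None:
        lines.append(f"# jspan={params.jspan} pid={params.pid} "
                     f"anchor_len={params.anchor_len} segment_size={params.segment_size} "
                     f"max_anchor_mismatches={params.max_anchor_mismatches}")
    for key, value in (extra or {}).items():
        lines.append(f"# {key}={value}")
    return lines


def write_ptes_bed(structure_calls: Sequence[StructureCall], path: str | Path,
                   params: FilterParams | None = None,
                   extra_header: Mapping[str, object] | None = None) -> None:
    """BED6 of called backsplice structures, sorted by (chrom, start)."""
    rows = []
    for call in structure_calls:
        start, end = call.construct.bed_interval
        rows.append((call.construct.chrom, start, end,
                     call.construct.junction_id, call.read_count,
                     call.construct.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for line in _header_lines(params, extra_header):
            fh.write(line + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_calls_bed(path: str | Path) -> list[tuple[str, str, int, int, int]]:
    """Parse a structure BED back into (chrom, strand, start, end, count)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"expected BED6, got {len(fields)} fields: {line!r}")
            out.append((fields[0], fields[5], int(fields[1]), int(fields[2]),
                        int(fields[4])))
    return out


def canonical_construct_library(transcriptome: TranscriptomeIndex,
                                genome: GenomeSource,
                                gene_ids: Iterable[str],
                                segment_size: int,
                                ) -> dict[str, JunctionConstruct]:
    """Junction models for all consecutive exon pairs of every transcript
    of the given genes, deduplicated by genomic junction key."""
    library: dict[tuple, JunctionConstruct] = {}
    for gene_id in sorted(set(gene_ids)):
        for tx in transcriptome.genes.get(gene_id, []):
            for i in range(tx.exon_count - 1):
                c = make_construct(genome, tx, i, i + 1,
                                   segment_size=segment_size, kind="canonical")
                library.setdefault(c.key, c)
    return {c.junction_id: c for c in library.values()}


def count_canonical_junctions(reads: Sequence[tuple[str, str]],
                              transcriptome: TranscriptomeIndex,
                              genome: GenomeSource,
                              ptes_genes: Iterable[str],
                              params: FilterParams = FilterParams(),
                              align_config: AlignConfig = AlignConfig(),
                              ) -> list[dict]:
    """Read counts over canonical junctions of backsplice-bearing genes.

    A read counts toward a junction when its best end-to-end placement
    on the canonical junction models is unambiguous (one junction key),
    spans the junction, and passes the JSpan and PID thresholds. The
    competitive filters do not apply: canonical reads align perfectly to
    the transcriptome by construction.
    """
    gene_ids = sorted(set(ptes_genes))
    library = canonical_construct_library(transcriptome, genome, gene_ids,
                                          params.segment_size)
    counts: dict[tuple, int] = {c.key: 0 for c in library.values()}
    if library and reads:
        k = min(10, min(len(c.sequence) for c in library.values()))
        index = ReferenceIndex({cid: c.sequence for cid, c in library.items()}, k=k)
        placements = align_full(reads, index, align_config)
        for rid, seq in reads:
            records = [r for r in placements[rid] if r.mapped]
            if not records:
                continue
            keys = {library[r.reference_id].key for r in records}
            if len(keys) != 1:
                continue
            rec = records[0]
            construct = library[rec.reference_id]
            profile = profile_from_record(rec, seq)
            jo = construct.junction_offset
            if jspan_pass(profile, jo, params.jspan, params.jspan_per_side) \
                    and pid_pass(profile, jo, params.pid):
                counts[construct.key] += 1
    records_out = []
    for gene_id in gene_ids:
        for tx in transcriptome.genes.get(gene_id, []):
            for i in range(tx.exon_count - 1):
                donor_exon, acceptor_exon = tx.exons[i], tx.exons[i + 1]
                key = junction_key(tx.chrom, tx.strand, donor_exon, acceptor_exon)
                start, end = junction_sites(tx.strand, donor_exon, acceptor_exon)
                records_out.append({
                    "gene_id": gene_id, "transcript_id": tx.transcript_id,
                    "chrom": tx.chrom, "junction_start": start,
                    "junction_end": end, "strand": tx.strand,
                    "count": counts.get(key, 0),
                })
    return records_out


def write_canonical_counts(records: Sequence[dict], path: str | Path,
                           params: FilterParams | None = None,
                           extra_header: Mapping[str, object] | None = None) -> None:
    cols = ["gene_id", "transcript_id", "chrom", "junction_start",
            "junction_end", "strand", "count"]
    with open(path, "w") as fh:
        for line in _header_lines(params, extra_header):
            fh.write(line + "\n")
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            fh.write("\t".join(str(rec[c]) for c in cols) + "\n")


def write_verdicts(verdicts: Sequence[FilterVerdict], path: str | Path) -> None:
    cols = ["read_id", "construct_id", "nm_construct", "nm_genome",
            "nm_transcriptome", "pid_donor", "pid_acceptor", "failed_genomic",
            "failed_transcriptomic", "failed_jspan", "failed_pid",
            "ambiguous", "retained"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for v in verdicts:
            row = [v.read_id, v.construct_id, v.nm_construct, v.nm_genome,
                   v.nm_transcriptome,
                   f"{v.pid_donor:.2f}" if v.pid_donor is not None else None,
                   f"{v.pid_acceptor:.2f}" if v.pid_acceptor is not None else None,
                   int(v.failed_genomic), int(v.failed_transcriptomic),
                   int(v.failed_jspan), int(v.failed_pid), int(v.ambiguous),
                   int(v.retained)]
            fh.write("\t".join("." if x is None else str(x) for x in row) + "\n")
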