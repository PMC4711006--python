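"""Transcript models, genome access and junction construct building.

The annotated transcriptome is supplied as BED12 (one record per
transcript); the genome as FASTA. Exon order is transcript order
(5'->3'), i.e. reverse genomic order on the minus strand. All
coordinates are 0-based half-open (BED convention) throughout.

A *construct* is the sequence model of a splice junction: the last
``segment_size`` bases of the donor exon followed by the first
``segment_size`` bases of the acceptor exon (the full exon when it is
shorter than the segment). Backsplice (PTES) constructs join a
downstream donor exon to an upstream -- or the same -- acceptor exon;
canonical constructs join consecutive exons of a linear transcript.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

DEFAULT_SEGMENT_SIZE = 65

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class BedParseError(ValueError):
    """Malformed BED12 record; carries the offending line and field."""

    def __init__(self, line_number: int, field_name: str, message: str):
        self.line_number = line_number
        self.field_name = field_name
        super().__init__(f"BED12 line {line_number}, field '{field_name}': {message}")


class ReferenceMismatchError(KeyError):
    """A chromosome named in the annotation is absent from the genome."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: strand and exons ordered 5'->3' in transcript space."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        genomic = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(genomic, genomic[1:]):
            if e0 > s1:
                raise ValueError("exons overlap")
        for s, e in self.exons:
            if e <= s:
                raise ValueError("empty exon interval")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError("exon order inconsistent with strand")

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    def cumulative_offsets(self) -> tuple[int, ...]:
        """Transcript-coordinate start offset of each exon, plus total length."""
        offs = [0]
        for length in self.exon_lengths():
            offs.append(offs[-1] + length)
        return tuple(offs)

    @property
    def length(self) -> int:
        return sum(self.exon_lengths())

    def offset_to_exon(self, offset: int) -> tuple[int, int]:
        """Map a transcript-coordinate offset to (exon index, genomic position)."""
        cum = self.cumulative_offsets()
        if not 0 <= offset < cum[-1]:
            raise IndexError(f"offset {offset} outside transcript {self.transcript_id}")
        for i in range(self.exon_count):
            if cum[i] <= offset < cum[i + 1]:
                within = offset - cum[i]
                s, e = self.exons[i]
                gpos = s + within if self.strand == "+" else e - 1 - within
                return i, gpos
        raise AssertionError("unreachable")

    def containing_exon(self, offset: int, length: int) -> int | None:
        """Exon index fully containing [offset, offset+length) in transcript
        coordinates, or None if the interval straddles a splice junction."""
        cum = self.cumulative_offsets()
        if offset < 0 or offset + length > cum[-1]:
            return None
        for i in range(self.exon_count):
            if cum[i] <= offset and offset + length <= cum[i + 1]:
                return i
        return None


def default_gene_key(name: str) -> str:
    """Gene identity from a BED name: the part before the first '|'."""
    return name.split("|", 1)[0]


class TranscriptomeIndex:
    """Transcript lookup by transcript id and by gene id."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, list[TranscriptModel]] = {}
        for tx in transcripts:
            if tx.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript id {tx.transcript_id!r}")
            self.transcripts[tx.transcript_id] = tx
            self.genes.setdefault(tx.gene_id, []).append(tx)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def gene_of(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].gene_id


def _parse_int(value: str, line_no: int, field_name: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise BedParseError(line_no, field_name, f"not an integer: {value!r}") from None


def _parse_int_list(value: str, line_no: int, field_name: str) -> list[int]:
    items = [v for v in value.strip().split(",") if v != ""]
    return [_parse_int(v, line_no, field_name) for v in items]


def load_transcriptome(
    source: str | Path | Iterable[str],
    gene_key: str | Callable[[str], str] | None = None,
) -> TranscriptomeIndex:
    """Parse BED12 into a :class:`TranscriptomeIndex`.

    ``gene_key`` extracts the gene identifier from the BED name field:
    a callable, or a regex whose first group is the gene id. Default:
    name up to the first ``|`` (whole name if none).
    """
    if gene_key is None:
        key_fn = default_gene_key
    elif callable(gene_key):
        key_fn = gene_key
    else:
        pattern = re.compile(gene_key)

        def key_fn(name: str, _p=pattern) -> str:
            m = _p.search(name)
            return m.group(1) if m and m.groups() else name

    if isinstance(source, (str, Path)):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)

    transcripts = []
    for line_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 12:
            raise BedParseError(line_no, "record", f"expected 12 fields, got {len(fields)}")
        chrom = fields[0]
        chrom_start = _parse_int(fields[1], line_no, "chromStart")
        chrom_end = _parse_int(fields[2], line_no, "chromEnd")
        name = fields[3]
        strand = fields[5]
        if strand not in "+-":
            raise BedParseError(line_no, "strand", f"expected '+' or '-', got {strand!r}")
        block_count = _parse_int(fields[9], line_no, "blockCount")
        block_sizes = _parse_int_list(fields[10], line_no, "blockSizes")
        block_starts = _parse_int_list(fields[11], line_no, "blockStarts")
        if len(block_sizes) != block_count:
            raise BedParseError(line_no, "blockSizes",
                                f"{len(block_sizes)} sizes for blockCount {block_count}")
        if len(block_starts) != block_count:
            raise BedParseError(line_no, "blockStarts",
                                f"{len(block_starts)} starts for blockCount {block_count}")
        if block_starts and block_starts[0] != 0:
            raise BedParseError(line_no, "blockStarts", "first blockStart must be 0")
        exons_genomic = []
        prev_end = None
        for bs, sz in zip(block_starts, block_sizes):
            if sz < 1:
                raise BedParseError(line_no, "blockSizes", f"block size {sz} < 1")
            s = chrom_start + bs
            e = s + sz
            if e > chrom_end:
                raise BedParseError(line_no, "blockSizes",
                                    f"block [{s},{e}) extends past chromEnd {chrom_end}")
            if prev_end is not None and s < prev_end:
                raise BedParseError(line_no, "blockStarts", "blocks overlap or unsorted")
            prev_end = e
            exons_genomic.append((s, e))
        if exons_genomic and exons_genomic[-1][1] != chrom_end:
            raise BedParseError(line_no, "blockSizes",
                                "last block must end at chromEnd")
        exons = tuple(exons_genomic if strand == "+" else exons_genomic[::-1])
        transcripts.append(TranscriptModel(
            transcript_id=name, gene_id=key_fn(name),
            chrom=chrom, strand=strand, exons=exons,
        ))
    return TranscriptomeIndex(transcripts)


class GenomeSource:
    """Random access to genome sequence, from an in-memory dict or a
    FASTA file (via pyfaidx)."""

    def __init__(self, source: str | Path | Mapping[str, str]):
        if isinstance(source, (str, Path)):
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source))
            self._dict = None
        else:
            self._fasta = None
            self._dict = dict(source)

    def chrom_length(self, chrom: str) -> int:
        if self._dict is not None:
            if chrom not in self._dict:
                raise ReferenceMismatchError(chrom)
            return len(self._dict[chrom])
        if chrom not in self._fasta:
            raise ReferenceMismatchError(chrom)
        return len(self._fasta[chrom])

    def __contains__(self, chrom: str) -> bool:
        try:
            self.chrom_length(chrom)
            return True
        except ReferenceMismatchError:
            return False

    def chroms(self) -> list[str]:
        if self._dict is not None:
            return list(self._dict)
        return list(self._fasta.keys())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        length = self.chrom_length(chrom)
        if not (0 <= start < end <= length):
            raise IndexError(
                f"interval [{start},{end}) out of bounds for {chrom} (length {length})")
        if self._dict is not None:
            return self._dict[chrom][start:end].upper()
        return str(self._fasta[chrom][start:end]).upper()


def exon_sequence(genome: GenomeSource, transcript: TranscriptModel,
                  exon_index: int) -> str:
    """Exon sequence in transcript orientation (reverse complement on '-')."""
    s, e = transcript.exons[exon_index]
    seq = genome.fetch(transcript.chrom, s, e)
    return reverse_complement(seq).upper() if transcript.strand == "-" else seq


def build_ptes_construct(donor_exon_seq: str, acceptor_exon_seq: str,
                         segment_size: int = DEFAULT_SEGMENT_SIZE) -> tuple[str, int]:
    """Join the donor-exon suffix to the acceptor-exon prefix.

    Returns ``(sequence, junction_offset)``; the junction lies between
    positions ``junction_offset - 1`` and ``junction_offset``. Exons
    shorter than ``segment_size`` contribute their full sequence.
    """
    if segment_size < 1:
        raise ValueError("segment_size must be >= 1")
    if not donor_exon_seq or not acceptor_exon_seq:
        raise ValueError("exon sequences must be non-empty")
    donor_seg = donor_exon_seq[-min(segment_size, len(donor_exon_seq)):]
    acceptor_seg = acceptor_exon_seq[:min(segment_size, len(acceptor_exon_seq))]
    return donor_seg + acceptor_seg, len(donor_seg)


def junction_sites(strand: str, donor_exon: tuple[int, int],
                   acceptor_exon: tuple[int, int]) -> tuple[int, int]:
    """Genomic (start, end) of the junction interval: acceptor 5' splice
    site to donor 3' splice site, ordered start < end."""
    donor_site = donor_exon[1] if strand == "+" else donor_exon[0]
    acceptor_site = acceptor_exon[0] if strand == "+" else acceptor_exon[1]
    return min(donor_site, acceptor_site), max(donor_site, acceptor_site)


def junction_key(chrom: str, strand: str, donor_exon: tuple[int, int],
                 acceptor_exon: tuple[int, int]) -> tuple[str, str, int, int]:
    start, end = junction_sites(strand, donor_exon, acceptor_exon)
    return (chrom, strand, start, end)


@dataclass(frozen=True)
class JunctionConstruct:
    """Sequence model of one splice junction (backsplice or canonical)."""

    junction_id: str
    gene_id: str
    chrom: str
    strand: str
    donor_exon: tuple[int, int]
    acceptor_exon: tuple[int, int]
    sequence: str
    junction_offset: int
    segment_size: int = DEFAULT_SEGMENT_SIZE
    kind: str = "ptes"  # 'ptes' | 'canonical'

    @property
    def key(self) -> tuple[str, str, int, int]:
        return junction_key(self.chrom, self.strand, self.donor_exon, self.acceptor_exon)

    @property
    def bed_interval(self) -> tuple[int, int]:
        return junction_sites(self.strand, self.donor_exon, self.acceptor_exon)


# Backwards-friendly aliases matching domain vocabulary.
PTESConstruct = JunctionConstruct
CanonicalJunctionModel = JunctionConstruct


def make_descriptor(gene_id: str, chrom: str, strand: str,
                    donor_exon: tuple[int, int], acceptor_exon: tuple[int, int]) -> str:
    start, end = junction_sites(strand, donor_exon, acceptor_exon)
    return f"{gene_id}|{chrom}|{strand}|{start}|{end}"


def make_construct(genome: GenomeSource, transcript: TranscriptModel,
                   donor_index: int, acceptor_index: int,
                   segment_size: int = DEFAULT_SEGMENT_SIZE,
                   kind: str = "ptes") -> JunctionConstruct:
    """Build the junction construct for two exons of one transcript.

    For ``kind='ptes'`` the donor is the transcript-downstream exon
    (``donor_index >= acceptor_index``); for ``kind='canonical'`` the
    acceptor immediately follows the donor.
    """
    if kind == "ptes" and donor_index < acceptor_index:
        raise ValueError("backsplice requires donor_index >= acceptor_index")
    if kind == "canonical" and acceptor_index != donor_index + 1:
        raise ValueError("canonical junction requires acceptor = donor + 1")
    donor_seq = exon_sequence(genome, transcript, donor_index)
    acceptor_seq = exon_sequence(genome, transcript, acceptor_index)
    seq, offset = build_ptes_construct(donor_seq, acceptor_seq, segment_size)
    donor_exon = transcript.exons[donor_index]
    acceptor_exon = transcript.exons[acceptor_index]
    return JunctionConstruct(
        junction_id=make_descriptor(transcript.gene_id, transcript.chrom,
                                    transcript.strand, donor_exon, acceptor_exon),
        gene_id=transcript.gene_id, chrom=transcript.chrom, strand=transcript.strand,
        donor_exon=donor_exon, acceptor_exon=acceptor_exon,
        sequence=seq, junction_offset=offset, segment_size=segment_size, kind=kind,
    )


def write_constructs_fasta(constructs: Iterable[JunctionConstruct],
                           path: str | Path) -> None:
    """Write a construct library as FASTA; the header carries the metadata
    needed to reload the library for guided runs."""
    with open(path, "w") as fh:
        for c in constructs:
            fh.write(
                f">{c.junction_id} offset={c.junction_offset} kind={c.kind} "
                f"donor={c.donor_exon[0]}-{c.donor_exon[1]} "
                f"acceptor={c.acceptor_exon[0]}-{c.acceptor_exon[1]} "
                f"segment={c.segment_size}\n{c.sequence}\n")


def read_constructs_fasta(path: str | Path) -> dict[str, JunctionConstruct]:
    """Reload a construct library written by :func:`write_constructs_fasta`."""
    from Bio import SeqIO

    constructs: dict[str, JunctionConstruct] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        attrs = dict(kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv)
        desc = rec.id
        parts = desc.split("|")
        if len(parts) != 5:
            raise ValueError(f"construct id {desc!r} is not a junction descriptor")
        gene_id, chrom, strand = parts[0], parts[1], parts[2]
        d_lo, d_hi = (int(x) for x in attrs["donor"].split("-"))
        a_lo, a_hi = (int(x) for x in attrs["acceptor"].split("-"))
        constructs[desc] = JunctionConstruct(
            junction_id=desc, gene_id=gene_id, chrom=chrom, strand=strand,
            donor_exon=(d_lo, d_hi), acceptor_exon=(a_lo, a_hi),
            sequence=str(rec.seq).upper(),
            junction_offset=int(attrs["offset"]),
            segment_size=int(attrs.get("segment", DEFAULT_SEGMENT_SIZE)),
            kind=attrs.get("kind", "ptes"),
        )
    return constructs


def spliced_sequence(genome: GenomeSource, transcript: TranscriptModel) -> str:
    """Full transcript sequence (exons concatenated in transcript order)."""
    return "".join(exon_sequence(genome, transcript, i)
                   for i in range(transcript.exon_count))
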