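"""Domain types and table readers/writers shared across the pipeline.

All tabular alignment inputs (metagenome-vs-phageome alignments, annotation
hits, POG match tables, prokaryote hit tables) use the 12-column BLAST
tabular dialect (``outfmt 6``): qseqid, sseqid, pident, length, mismatch,
gapopen, qstart, qend, sstart, send, evalue, bitscore.  Gene tables and
mapping summaries are plain TSV.  Coordinates are 1-based inclusive
throughout; alignment records are normalized so that ``q_start <= q_end``,
with the strand inferred from the subject coordinate order.

Comment lines starting with ``#`` and blank lines are skipped in every
tabular reader.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

from Bio import SeqIO

DATABASE_TAGS = ("KO", "Pfam", "uPOG", "viral_family", "hallmark")


class FormatError(ValueError):
    """A malformed input file (wrong column count, bad value, empty file)."""


class ConfigurationError(ValueError):
    """An invalid parameter (unknown database tag, bad threshold)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contig:
    """An assembled contig.

    ``sequence`` may be ``None`` when only lengths are known (most of the
    pipeline operates on tables, not bases); when present it is an upper-case
    DNA string over {A, C, G, T, N} and ``length == len(sequence)``.
    """

    id: str
    sample_id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise FormatError(f"contig {self.id!r}: non-positive length {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise FormatError(
                f"contig {self.id!r}: length {self.length} != sequence "
                f"length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class GeneCall:
    """A predicted gene on a contig; 1-based inclusive coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: invalid coordinates "
                f"{self.start}..{self.end} (1-based, start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: strand must be '+' or '-'")


@dataclass(frozen=True)
class AnnotationHit:
    """One homology hit of a gene against a reference database."""

    gene_id: str
    database: str
    subject_id: str
    evalue: float
    bit_score: float
    identity_pct: float
    aln_length: int

    def __post_init__(self) -> None:
        if self.database not in DATABASE_TAGS:
            raise ConfigurationError(
                f"unknown database tag {self.database!r}; expected one of {DATABASE_TAGS}"
            )
        if self.evalue < 0:
            raise FormatError(f"hit {self.gene_id!r}: negative e-value {self.evalue}")
        if not 0 <= self.identity_pct <= 100:
            raise FormatError(
                f"hit {self.gene_id!r}: identity {self.identity_pct} outside [0, 100]"
            )


@dataclass(frozen=True)
class MappingSummary:
    """Per-contig read-mapping summary for one sample.

    ``relative_abundance`` is mapped reads over total reads in the sample;
    ``depth`` is mapped reads over contig length (reads per bp).  The
    upstream read counting applies a 99%-identity read filter; counts are
    accepted here as given.
    """

    contig_id: str
    sample_id: str
    mapped_reads: int
    total_reads_in_sample: int
    relative_abundance: float
    depth: float

    @classmethod
    def from_counts(
        cls,
        contig_id: str,
        sample_id: str,
        mapped_reads: int,
        total_reads_in_sample: int,
        contig_length: int,
    ) -> "MappingSummary":
        if total_reads_in_sample <= 0:
            raise FormatError(
                f"sample {sample_id!r}: total read count must be positive"
            )
        if mapped_reads < 0:
            raise FormatError(f"contig {contig_id!r}: negative mapped-read count")
        return cls(
            contig_id=contig_id,
            sample_id=sample_id,
            mapped_reads=mapped_reads,
            total_reads_in_sample=total_reads_in_sample,
            relative_abundance=mapped_reads / total_reads_in_sample,
            depth=mapped_reads / contig_length,
        )


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment hit in the 12-column tabular dialect.

    Query coordinates are normalized forward (``q_start <= q_end``); a
    subject coordinate pair in descending order marks a minus-strand hit
    (``minus_strand=True``) and is stored as given.
    """

    query_id: str
    subject_id: str
    identity_pct: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    minus_strand: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.aln_length <= 0:
            raise FormatError(
                f"alignment {self.query_id!r} vs {self.subject_id!r}: "
                f"non-positive length {self.aln_length}"
            )
        if self.evalue < 0:
            raise FormatError(
                f"alignment {self.query_id!r} vs {self.subject_id!r}: negative e-value"
            )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _open(path: str | Path | TextIO) -> TextIO:
    if isinstance(path, (str, Path)):
        return open(path, "rt")
    return path


def _data_lines(handle: TextIO) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping blanks/comments."""
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line


def read_fasta(path: str | Path | TextIO, sample_id: str = "") -> list[Contig]:
    """Read contigs from a FASTA file.

    Sequences are upper-cased; ``N`` is allowed.  Raises
    :class:`FormatError` on an empty file or a malformed record.
    """
    handle = _open(path)
    close = isinstance(path, (str, Path))
    try:
        contigs: list[Contig] = []
        seen: set[str] = set()
        for record in SeqIO.parse(handle, "fasta"):
            seq = str(record.seq).upper()
            if not record.id:
                raise FormatError("FASTA record with empty header")
            if not seq:
                raise FormatError(f"FASTA record {record.id!r} has an empty sequence")
            if record.id in seen:
                raise FormatError(f"duplicate FASTA id {record.id!r}")
            seen.add(record.id)
            contigs.append(
                Contig(id=record.id, sample_id=sample_id, length=len(seq), sequence=seq)
            )
        if not contigs:
            raise FormatError("empty FASTA file (no records)")
        return contigs
    finally:
        if close:
            handle.close()


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for c in contigs:
            if c.sequence is None:
                raise ConfigurationError(f"contig {c.id!r} has no sequence to write")
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


def _parse_alignment_row(fields: list[str], lineno: int) -> AlignmentRecord:
    if len(fields) != 12:
        raise FormatError(
            f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
        )
    try:
        q_start, q_end = int(fields[6]), int(fields[7])
        s_start, s_end = int(fields[8]), int(fields[9])
        if q_start > q_end:  # store query forward, flip both sides
            q_start, q_end = q_end, q_start
            s_start, s_end = s_end, s_start
        return AlignmentRecord(
            query_id=fields[0],
            subject_id=fields[1],
            identity_pct=float(fields[2]),
            aln_length=int(fields[3]),
            mismatches=int(fields[4]),
            gap_opens=int(fields[5]),
            q_start=q_start,
            q_end=q_end,
            s_start=s_start,
            s_end=s_end,
            evalue=float(fields[10]),
            bit_score=float(fields[11]),
            minus_strand=s_start > s_end,
        )
    except ValueError as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"line {lineno}: {exc}") from exc


def read_alignment_table(path: str | Path | TextIO) -> list[AlignmentRecord]:
    """Read a 12-column tabular alignment file (BLAST ``outfmt 6`` dialect)."""
    handle = _open(path)
    close = isinstance(path, (str, Path))
    try:
        return [
            _parse_alignment_row(line.split("\t"), lineno)
            for lineno, line in _data_lines(handle)
        ]
    finally:
        if close:
            handle.close()


def write_alignment_table(
    records: Iterable[AlignmentRecord], path: str | Path
) -> None:
    with open(path, "wt") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id,
                        r.subject_id,
                        r.identity_pct,
                        r.aln_length,
                        r.mismatches,
                        r.gap_opens,
                        r.q_start,
                        r.q_end,
                        r.s_start,
                        r.s_end,
                        r.evalue,
                        r.bit_score,
                    )
                )
                + "\n"
            )


def read_gene_table(path: str | Path | TextIO) -> list[GeneCall]:
    """Read a gene table TSV: gene_id, contig_id, start, end, strand.

    1-based inclusive coordinates; duplicate gene ids are rejected.
    """
    handle = _open(path)
    close = isinstance(path, (str, Path))
    try:
        genes: list[GeneCall] = []
        seen: set[str] = set()
        for lineno, line in _data_lines(handle):
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(
                    f"line {lineno}: expected 5 columns (gene_id, contig_id, "
                    f"start, end, strand), got {len(fields)}"
                )
            gene_id = fields[0]
            if gene_id in seen:
                raise FormatError(f"line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                gene = GeneCall(
                    gene_id=gene_id,
                    contig_id=fields[1],
                    start=int(fields[2]),
                    end=int(fields[3]),
                    strand=fields[4],
                )
            except ValueError as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"line {lineno}: {exc}") from exc
            genes.append(gene)
        return genes
    finally:
        if close:
            handle.close()


def write_gene_table(genes: Iterable[GeneCall], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.contig_id}\t{g.start}\t{g.end}\t{g.strand}\n")


def read_annotation_hits(
    path: str | Path | TextIO, database_tag: str
) -> list[AnnotationHit]:
    """Read annotation hits from a tabular alignment file, tagging each with
    ``database_tag``.

    No e-value filtering happens here; thresholding is the feature module's
    responsibility.
    """
    if database_tag not in DATABASE_TAGS:
        raise ConfigurationError(
            f"unknown database tag {database_tag!r}; expected one of {DATABASE_TAGS}"
        )
    records = read_alignment_table(path)
    return [
        AnnotationHit(
            gene_id=r.query_id,
            database=database_tag,
            subject_id=r.subject_id,
            evalue=r.evalue,
            bit_score=r.bit_score,
            identity_pct=r.identity_pct,
            aln_length=r.aln_length,
        )
        for r in records
    ]


def read_mapping_summary(
    path: str | Path | TextIO,
    totals: dict[str, int],
    contig_lengths: dict[str, int],
) -> list[MappingSummary]:
    """Read per-contig mapped-read counts and derive abundance and depth.

    The TSV has columns contig_id, sample_id, mapped_reads.  ``totals`` maps
    sample id to total read count; ``contig_lengths`` maps contig id to
    length in bp.  Unknown contigs and zero sample totals are errors.
    """
    handle = _open(path)
    close = isinstance(path, (str, Path))
    try:
        summaries: list[MappingSummary] = []
        for lineno, line in _data_lines(handle):
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"line {lineno}: expected 3 columns (contig_id, sample_id, "
                    f"mapped_reads), got {len(fields)}"
                )
            contig_id, sample_id = fields[0], fields[1]
            if contig_id not in contig_lengths:
                raise FormatError(f"line {lineno}: unknown contig id {contig_id!r}")
            if sample_id not in totals:
                raise FormatError(f"line {lineno}: unknown sample id {sample_id!r}")
            summaries.append(
                MappingSummary.from_counts(
                    contig_id=contig_id,
                    sample_id=sample_id,
                    mapped_reads=int(fields[2]),
                    total_reads_in_sample=totals[sample_id],
                    contig_length=contig_lengths[contig_id],
                )
            )
        return summaries
    finally:
        if close:
            handle.close()


def write_mapping_counts(
    summaries: Iterable[MappingSummary], path: str | Path
) -> None:
    with open(path, "wt") as fh:
        for m in summaries:
            fh.write(f"{m.contig_id}\t{m.sample_id}\t{m.mapped_reads}\n")
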