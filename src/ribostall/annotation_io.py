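"""Readers/writers for CDS FASTA, footprint BED and count tables.

Coordinate conventions
----------------------
All footprint coordinates are 0-based half-open nucleotide positions relative
to the first nucleotide of the start codon (the natural BED frame for
transcript-coordinate alignments). Codon indices are 0-based internally; the
1-based convention appears only where the ">90 codons" occupancy cutoff is
applied downstream.

Validation policy: lenient by default (records or rows that violate
invariants are skipped with a logged warning and counted); ``strict=True``
escalates every such condition to an exception.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import START_CODON, STOP_CODONS

logger = logging.getLogger(__name__)

DEFAULT_LENGTH_BOUNDS = (17, 35)


class ValidationError(ValueError):
    """A record or row violates a domain invariant."""


class ParseError(ValueError):
    """A file is structurally malformed (carries the offending line number)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class TranscriptModel:
    """One coding sequence: the coordinate frame for all downstream analysis.

    The sequence must be a complete CDS — start codon first, a single stop
    codon last, and no internal stop — so that codon index ``k`` always means
    "the k-th codon of the open reading frame" (0-based).
    """

    transcript_id: str
    cds_seq: str

    def __post_init__(self) -> None:
        seq = self.cds_seq.upper()
        object.__setattr__(self, "cds_seq", seq)
        if not seq or len(seq) % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length {len(seq)} is not a "
                "positive multiple of 3"
            )
        if set(seq) - set("ACGT"):
            raise ValidationError(
                f"{self.transcript_id}: non-ACGT characters in CDS"
            )
        codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
        if codons[0] != START_CODON:
            raise ValidationError(f"{self.transcript_id}: CDS does not start with ATG")
        if codons[-1] not in STOP_CODONS:
            raise ValidationError(f"{self.transcript_id}: CDS does not end in a stop codon")
        if any(c in STOP_CODONS for c in codons[:-1]):
            raise ValidationError(f"{self.transcript_id}: internal stop codon")
        object.__setattr__(self, "_codons", codons)

    @property
    def codons(self) -> tuple[str, ...]:
        return self._codons  # type: ignore[attr-defined]

    @property
    def n_codons(self) -> int:
        return len(self.cds_seq) // 3


class TranscriptSet(Mapping[str, TranscriptModel]):
    """Immutable-ish mapping transcript_id -> TranscriptModel."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()):
        self._by_id: dict[str, TranscriptModel] = {}
        for t in transcripts:
            self.add(t)

    def add(self, transcript: TranscriptModel) -> None:
        if transcript.transcript_id in self._by_id:
            raise ValidationError(f"duplicate transcript id {transcript.transcript_id!r}")
        self._by_id[transcript.transcript_id] = transcript

    def __getitem__(self, key: str) -> TranscriptModel:
        return self._by_id[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._by_id)

    def __len__(self) -> int:
        return len(self._by_id)

    def merged(self, other: "TranscriptSet") -> "TranscriptSet":
        return TranscriptSet(list(self._by_id.values()) + list(other._by_id.values()))


@dataclass(frozen=True, slots=True)
class FootprintAlignment:
    """One ribosome-protected fragment in transcript coordinates.

    ``start`` is the 5' end, 0-based relative to the first nt of the start
    codon. No invariant is enforced at construction: offset calibration
    legitimately handles reads with negative starts (5' ends upstream of the
    ATG); bounds are enforced by :func:`read_footprints_bed`.
    """

    transcript_id: str
    start: int
    length: int


@dataclass(frozen=True)
class GeneCounts:
    gene_id: str
    rpf_count: int
    rna_count: int

    def __post_init__(self) -> None:
        for name in ("rpf_count", "rna_count"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValidationError(
                    f"{self.gene_id}: {name}={v!r} is not a non-negative integer"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_cds_fasta(path: str | Path, strict: bool = False) -> TranscriptSet:
    """Load a CDS FASTA (one record per transcript, CDS only, no UTRs).

    Records violating the TranscriptModel invariants are skipped with a
    warning (``strict=True`` raises instead).
    """
    transcripts = TranscriptSet()
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        try:
            transcripts.add(TranscriptModel(record.id, str(record.seq)))
        except ValidationError as exc:
            if strict:
                raise
            logger.warning("skipping FASTA record: %s", exc)
    if n_records == 0:
        logger.warning("empty FASTA: %s", path)
    logger.info("read %d/%d CDS records from %s", len(transcripts), n_records, path)
    return transcripts


def write_cds_fasta(transcripts: TranscriptSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.cds_seq), id=tid, description="")
        for tid, t in sorted(transcripts.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

@dataclass
class LoadResult:
    """Footprints plus the loading ledger (rows_in == loaded + dropped)."""

    footprints: list[FootprintAlignment] = field(default_factory=list)
    rows_in: int = 0
    drop_reasons: Counter = field(default_factory=Counter)

    @property
    def rows_loaded(self) -> int:
        return len(self.footprints)

    @property
    def rows_dropped(self) -> int:
        return sum(self.drop_reasons.values())

    def __iter__(self) -> Iterator[FootprintAlignment]:
        return iter(self.footprints)

    def __len__(self) -> int:
        return len(self.footprints)


def read_footprints_bed(
    path: str | Path,
    transcripts: TranscriptSet,
    strict: bool = False,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> LoadResult:
    """Read footprint alignments from BED6 with chrom = transcript_id.

    Coordinates are 0-based half-open in transcript nt space. Structural
    problems (wrong column count, non-integer coordinates, end <= start) are
    always errors with a line number; semantic problems (unknown transcript,
    out-of-bounds interval, length outside ``length_bounds``, "-" strand) are
    dropped and counted in lenient mode, errors in strict mode.
    """
    lo, hi = length_bounds
    result = LoadResult()

    def drop(reason: str, line_no: int, detail: str) -> None:
        if strict:
            raise ValidationError(f"line {line_no}: {detail}")
        result.drop_reasons[reason] += 1
        logger.debug("dropping BED row (%s): line %d: %s", reason, line_no, detail)

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"expected >=3 BED columns, got {len(fields)}", line_no)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", line_no) from None
            if end <= start:
                raise ValidationError(f"line {line_no}: end {end} <= start {start}")
            result.rows_in += 1
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand == "-":
                if strict:
                    raise ValidationError(
                        f"line {line_no}: '-' strand row on transcript coordinates"
                    )
                logger.warning("line %d: '-' strand tolerated on %s", line_no, chrom)
            if chrom not in transcripts:
                drop("unknown_transcript", line_no, f"unknown transcript {chrom!r}")
                continue
            length = end - start
            if not (lo <= length <= hi):
                drop("length_out_of_bounds", line_no, f"length {length} outside {length_bounds}")
                continue
            if start < 0 or end > 3 * transcripts[chrom].n_codons:
                drop("out_of_bounds", line_no, f"[{start},{end}) outside CDS of {chrom}")
                continue
            result.footprints.append(FootprintAlignment(chrom, start, length))

    logger.info(
        "BED %s: %d rows in, %d loaded, %d dropped %s",
        path, result.rows_in, result.rows_loaded, result.rows_dropped,
        dict(result.drop_reasons),
    )
    return result


def write_footprints_bed(
    footprints: Iterable[FootprintAlignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for i, fp in enumerate(footprints):
            fh.write(
                f"{fp.transcript_id}\t{fp.start}\t{fp.start + fp.length}\tr{i}\t0\t+\n"
            )


# ---------------------------------------------------------------------------
# Count / result tables
# ---------------------------------------------------------------------------

def read_gene_counts_tsv(path: str | Path) -> list[GeneCounts]:
    """Read a gene_id / rpf_count / rna_count table."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "rpf_count", "rna_count"}
    if not required.issubset(df.columns):
        raise ParseError(f"missing columns {sorted(required - set(df.columns))} in {path}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate gene rows: {sorted(dup.unique())}")
    out = []
    for row in df.itertuples(index=False):
        for v in (row.rpf_count, row.rna_count):
            if float(v) != int(v) or int(v) < 0:
                raise ValidationError(f"{row.gene_id}: count {v!r} not a non-negative integer")
        out.append(GeneCounts(row.gene_id, int(row.rpf_count), int(row.rna_count)))
    return out


def write_gene_counts_tsv(counts: Iterable[GeneCounts], path: str | Path) -> None:
    df = pd.DataFrame(
        [(c.gene_id, c.rpf_count, c.rna_count) for c in counts],
        columns=["gene_id", "rpf_count", "rna_count"],
    ).sort_values("gene_id")
    df.to_csv(path, sep="\t", index=False)


def write_table(
    records: pd.DataFrame,
    path: str | Path,
    sort_by: str | list[str] | None = None,
    allow_empty: bool = False,
) -> None:
    """Write a result table as TSV: header, deterministic row/column order,
    "." for missing. Round-trips bit-identically through :func:`read_table`.
    """
    if records.empty and not allow_empty:
        raise ValidationError("refusing to write empty table (pass allow_empty=True)")
    df = records
    if sort_by is None and len(df.columns):
        sort_by = df.columns[0]
    if sort_by is not None and not df.empty:
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])
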