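"""FASTA input/output and the round-trip metadata header codec.

Barcoded records carry, inside their FASTA identifier, the list of
(alignment column, barcode id, original character) triples needed to undo
the barcoding after re-alignment.  The codec grammar is::

    header   := id | id "|CB:" entries
    entries  := entry (";" entry)*
    entry    := column "," barcode_id "," original_char

where ``column`` is the 1-based alignment column, ``barcode_id`` is a token
free of ``|;,`` and whitespace, and ``original_char`` is one residue letter
or ``-``.  The delimiters never occur in amino-acid alphabets, so the
header survives any aligner that preserves FASTA identifiers.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, List, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentShapeError,
    DuplicateIdError,
    EmptyInputError,
    InvalidMetadataError,
    MetadataParseError,
)

GAP = "-"
_RESIDUE_RE = re.compile(r"^[A-Z\-]+$")

MetaEntry = Tuple[int, str, str]  # (1-based column, barcode id, original char)


@dataclass
class SequenceRecord:
    """One (possibly gapped) protein sequence with a stable identifier."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise InvalidMetadataError(f"invalid record id: {self.id!r}")
        if not self.residues:
            raise EmptyInputError(f"record {self.id!r} has an empty sequence")
        if not _RESIDUE_RE.match(self.residues):
            raise InvalidMetadataError(
                f"record {self.id!r} contains characters outside A-Z/-"
            )

    def ungapped(self) -> str:
        """Residues with all gap characters removed."""
        return self.residues.replace(GAP, "")


@dataclass
class ProteinAlignment:
    """An ordered set of equal-length gapped sequences."""

    records: List[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentShapeError("an alignment needs at least 2 records")
        ncol = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != ncol:
                raise AlignmentShapeError(
                    f"record {rec.id!r} has length {len(rec.residues)}, "
                    f"expected {ncol}"
                )
        seen = set()
        for rec in self.records:
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    @property
    def ncol(self) -> int:
        return len(self.records[0].residues)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def record(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)

    def column(self, col: int) -> str:
        """Characters of 1-based column ``col``, in record order."""
        return "".join(rec.residues[col - 1] for rec in self.records)

    def drop_all_gap_columns(self) -> "ProteinAlignment":
        keep = [
            c for c in range(1, self.ncol + 1)
            if set(self.column(c)) != {GAP}
        ]
        recs = [
            SequenceRecord(
                rec.id,
                "".join(rec.residues[c - 1] for c in keep),
                rec.description,
            )
            for rec in self.records
        ]
        return ProteinAlignment(recs)


@dataclass
class BarcodeMetadata:
    """Ordered (column, barcode_id, original_char) triples for one record."""

    entries: List[MetaEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = [e[0] for e in self.entries]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise InvalidMetadataError("metadata columns must strictly increase")
        ids = [e[1] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise InvalidMetadataError("barcode ids must be unique per record")
        for col, bcid, char in self.entries:
            if col < 1:
                raise InvalidMetadataError(f"column {col} is not 1-based")
            _check_token(bcid)
            _check_original_char(char)

    def __bool__(self) -> bool:
        return bool(self.entries)

    def __iter__(self):
        return iter(self.entries)


def _check_token(token: str) -> None:
    if not token or re.search(r"[|;,\s]", token):
        raise InvalidMetadataError(f"invalid barcode id token: {token!r}")


def _check_original_char(char: str) -> None:
    if len(char) != 1 or not re.match(r"^[A-Z\-]$", char):
        raise InvalidMetadataError(
            f"original char must be one residue letter or '-', got {char!r}"
        )


def encode_metadata(record_id: str, meta: BarcodeMetadata) -> str:
    """Serialise ``meta`` into a whitespace-free FASTA identifier."""
    if any(c.isspace() for c in record_id) or "|" in record_id:
        raise InvalidMetadataError(
            f"record id may not contain whitespace or '|': {record_id!r}"
        )
    if not meta:
        return record_id
    body = ";".join(f"{col},{bcid},{char}" for col, bcid, char in meta)
    return f"{record_id}|CB:{body}"


def decode_metadata(header: str) -> Tuple[str, BarcodeMetadata]:
    """Invert :func:`encode_metadata`; headers without a block decode to
    empty metadata."""
    if "|CB:" not in header:
        if "|" in header:
            raise MetadataParseError(
                f"unrecognised '|' block in header {header!r} "
                f"(position {header.index('|')})"
            )
        return header, BarcodeMetadata([])
    record_id, _, body = header.partition("|CB:")
    entries: List[MetaEntry] = []
    for i, chunk in enumerate(body.split(";")):
        parts = chunk.split(",")
        if len(parts) != 3:
            raise MetadataParseError(
                f"metadata entry {i} ({chunk!r}) in {header!r} does not have "
                "3 comma-separated fields"
            )
        col_s, bcid, char = parts
        try:
            col = int(col_s)
        except ValueError:
            raise MetadataParseError(
                f"metadata entry {i}: column {col_s!r} is not an integer"
            ) from None
        entries.append((col, bcid, char))
    try:
        meta = BarcodeMetadata(entries)
    except InvalidMetadataError as exc:
        raise MetadataParseError(f"invalid metadata in {header!r}: {exc}") from exc
    return record_id, meta


def _parse_fasta(handle) -> List[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(handle, "fasta"):
        residues = str(rec.seq).upper().replace(".", GAP)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, residues, desc))
    return records


def read_fasta(path_or_stream) -> List[SequenceRecord]:
    """Read unaligned (or aligned) FASTA into records, without shape checks."""
    if hasattr(path_or_stream, "read"):
        records = _parse_fasta(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            records = _parse_fasta(fh)
    if not records:
        raise EmptyInputError("FASTA input contains no sequences")
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
    return records


def read_alignment(path_or_stream) -> ProteinAlignment:
    """Read an aligned FASTA file; all sequences must have equal length."""
    records = read_fasta(path_or_stream)
    lengths = {len(r.residues) for r in records}
    if len(lengths) > 1:
        ncol = len(records[0].residues)
        bad = next(r for r in records if len(r.residues) != ncol)
        raise AlignmentShapeError(
            f"record {bad.id!r} has length {len(bad.residues)}, but "
            f"{records[0].id!r} has length {ncol}"
        )
    return ProteinAlignment(records)


def write_fasta(records: Iterable[SequenceRecord],
                path_or_stream: Union[str, io.TextIOBase]) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    seqrecords = [
        SeqRecord(Seq(rec.residues), id=rec.id,
                  description=rec.description or "")
        for rec in records
    ]
    if hasattr(path_or_stream, "write"):
        SeqIO.write(seqrecords, path_or_stream, "fasta")
    else:
        with open(path_or_stream, "w") as fh:
            SeqIO.write(seqrecords, fh, "fasta")


def write_alignment(alignment: ProteinAlignment, path_or_stream) -> None:
    write_fasta(alignment.records, path_or_stream)
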