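"""Restore the original columns after re-alignment of barcoded sequences.

Each record's header names the barcodes it carries (see
:mod:`cysanchor.seqio`).  For every (record, barcode) pair the minimal
column span whose gap-stripped content equals the barcode is located —
aligners may have split a barcode with internal gaps — and the span is
replaced by the character the barcode displaced, placed at the span's
first column.  When all records place a barcode in the same span, the rest
of that span becomes all-gap and is removed, leaving the restored
residues in a single shared column; when records disagree the alignment
is still produced, with the disagreement reported as a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .barcode_design import Barcode, default_barcodes
from .errors import (
    AmbiguousBarcodeError,
    MissingBarcodeError,
    NoMetadataError,
)
from .seqio import (
    GAP,
    BarcodeMetadata,
    ProteinAlignment,
    SequenceRecord,
    decode_metadata,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BarcodeSpan:
    """Location of one barcode inside one realigned record."""

    record_id: str
    barcode_id: str
    start_column: int  # 1-based, inclusive
    end_column: int    # 1-based, inclusive
    internal_gap_count: int


@dataclass
class ReconstructionReport:
    """Per-barcode agreement status plus any warnings raised."""

    barcode_status: Dict[str, str] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    @property
    def all_aligned(self) -> bool:
        return all(s == "aligned" for s in self.barcode_status.values())


def _barcode_sequence_map(
    barcodes: Optional[Union[Sequence[Barcode], Mapping[str, str]]]
) -> Dict[str, str]:
    if barcodes is None:
        barcodes = default_barcodes()
    if isinstance(barcodes, Mapping):
        return dict(barcodes)
    return {bc.id: bc.sequence for bc in barcodes}


def _decode_all(alignment: ProteinAlignment
                ) -> List[Tuple[str, BarcodeMetadata, SequenceRecord]]:
    decoded = []
    for rec in alignment:
        record_id, meta = decode_metadata(rec.id)
        decoded.append((record_id, meta, rec))
    if not any(meta for _, meta, _ in decoded):
        raise NoMetadataError(
            "no record carries barcode metadata; nothing to reconstruct"
        )
    return decoded


def locate_barcodes(
    alignment: ProteinAlignment,
    barcodes: Optional[Union[Sequence[Barcode], Mapping[str, str]]] = None,
) -> List[BarcodeSpan]:
    """Find every expected barcode in the realigned records.

    For each (record, barcode-id-in-metadata) pair, returns the unique
    minimal column span whose gap-stripped content equals the barcode
    sequence.  A barcode that is absent (e.g. corrupted by the aligner) or
    that occurs more than once raises an error naming record and barcode.
    """
    seq_of = _barcode_sequence_map(barcodes)
    spans: List[BarcodeSpan] = []
    for record_id, meta, rec in _decode_all(alignment):
        # map residue ordinals to 1-based columns
        residue_cols = [i + 1 for i, ch in enumerate(rec.residues)
                        if ch != GAP]
        stripped = rec.ungapped()
        for _, bcid, _ in meta:
            if bcid not in seq_of:
                raise MissingBarcodeError(
                    f"record {record_id}: barcode id {bcid!r} is not in "
                    "the supplied barcode set"
                )
            bcseq = seq_of[bcid]
            first = stripped.find(bcseq)
            if first == -1:
                raise MissingBarcodeError(
                    f"record {record_id}: barcode {bcid} ({bcseq}) not "
                    "found (corrupted by the aligner?)"
                )
            if stripped.find(bcseq, first + 1) != -1:
                raise AmbiguousBarcodeError(
                    f"record {record_id}: barcode {bcid} ({bcseq}) occurs "
                    "more than once"
                )
            start = residue_cols[first]
            end = residue_cols[first + len(bcseq) - 1]
            spans.append(BarcodeSpan(
                record_id=record_id,
                barcode_id=bcid,
                start_column=start,
                end_column=end,
                internal_gap_count=(end - start + 1) - len(bcseq),
            ))
    return spans


def reconstruct(
    alignment: ProteinAlignment,
    barcodes: Optional[Union[Sequence[Barcode], Mapping[str, str]]] = None,
) -> Tuple[ProteinAlignment, ReconstructionReport]:
    """Exchange every barcode for the character it displaced.

    In each record the barcode's span is overwritten with the stored
    original character at the span's first column and gaps elsewhere;
    all-gap columns are then removed and metadata stripped from headers.
    When the aligner kept all copies of a barcode in one span (the
    designed behaviour) the restored residues share a single column; a
    record whose span disagrees with the others is reported as a warning,
    never an error — the alignment is still produced.
    """
    spans = locate_barcodes(alignment, barcodes)
    span_of = {(s.record_id, s.barcode_id): s for s in spans}
    report = ReconstructionReport()

    by_barcode: Dict[str, List[BarcodeSpan]] = {}
    for s in spans:
        by_barcode.setdefault(s.barcode_id, []).append(s)
    for bcid, group in sorted(by_barcode.items()):
        extents = {(s.start_column, s.end_column) for s in group}
        if len(extents) == 1:
            report.barcode_status[bcid] = "aligned"
        else:
            report.barcode_status[bcid] = "misaligned"
            modal = max(
                extents,
                key=lambda e: (sum(1 for s in group
                                   if (s.start_column, s.end_column) == e),
                               -e[0]),
            )
            offenders = sorted(
                s.record_id for s in group
                if (s.start_column, s.end_column) != modal
            )
            msg = (f"barcode {bcid}: spans disagree across records "
                   f"(outliers: {', '.join(offenders)})")
            report.warnings.append(msg)
            log.warning("%s", msg)

    out_records: List[SequenceRecord] = []
    for record_id, meta, rec in _decode_all(alignment):
        chars = list(rec.residues)
        for _, bcid, orig in meta:
            span = span_of[(record_id, bcid)]
            for col in range(span.start_column, span.end_column + 1):
                chars[col - 1] = GAP
            chars[span.start_column - 1] = orig
        out_records.append(
            SequenceRecord(record_id, "".join(chars), rec.description)
        )
    final = ProteinAlignment(out_records).drop_all_gap_columns()
    return final, report
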