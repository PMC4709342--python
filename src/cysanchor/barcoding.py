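"""Replace homologous-cysteine alignment columns with peptide barcodes.

Each selected alignment column is replaced, in every record, by a full
barcode sequence; the character the barcode displaced is stored both in a
:class:`BarcodeAssignment` ledger and in the record's FASTA header (see
:mod:`cysanchor.seqio`).  All gap characters are then stripped so the
inter-cysteine loops are free to re-align, while the barcodes pin the
anchored columns in place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .barcode_design import (
    Barcode,
    CollisionReport,
    check_collisions,
    default_barcodes,
)
from .errors import ColumnRangeError, DuplicateColumnError, MergeConflictError
from .seqio import (
    GAP,
    BarcodeMetadata,
    ProteinAlignment,
    SequenceRecord,
    encode_metadata,
)

log = logging.getLogger(__name__)


@dataclass
class BarcodeAssignment:
    """The round-trip ledger: which barcode replaced which column, and
    which character each record originally held there."""

    columns: List[int]
    barcode_for_column: Dict[int, Barcode]
    originals: Dict[Tuple[str, int], str]
    warnings: List[str] = field(default_factory=list)
    collision_report: Optional[CollisionReport] = None

    def barcode_sequences(self) -> Dict[str, str]:
        """Mapping barcode id -> barcode sequence for the assigned set."""
        return {bc.id: bc.sequence
                for bc in self.barcode_for_column.values()}


def _validate_columns(columns: Sequence[int], ncol: int) -> List[int]:
    cols = list(columns)
    if len(set(cols)) != len(cols):
        dup = next(c for c in cols if cols.count(c) > 1)
        raise DuplicateColumnError(f"column {dup} requested more than once")
    for c in cols:
        if not 1 <= c <= ncol:
            raise ColumnRangeError(
                f"column {c} out of range 1..{ncol} (columns are 1-based)"
            )
    return sorted(cols)


def apply_barcodes(
    alignment: ProteinAlignment,
    columns: Sequence[int],
    barcode_source: Optional[Sequence[Barcode]] = None,
) -> Tuple[List[SequenceRecord], BarcodeAssignment]:
    """Barcode the given 1-based alignment columns.

    Returns the gap-stripped, metadata-tagged records (unaligned, ready
    for re-alignment) and the :class:`BarcodeAssignment` ledger.  Barcodes
    are drawn in rank order from ``barcode_source`` (the canonical default
    pool when omitted), skipping any that collide with the input
    sequences.

    A record with a gap at a barcoded column still receives the barcode
    and stores ``'-'`` as its original character, which keeps the
    round trip exact; such records are flagged in ``warnings``.  Replacing
    a non-cysteine residue is allowed (anchoring works for any column of
    structurally homologous residues) but is also flagged.
    """
    cols = _validate_columns(columns, alignment.ncol)
    pool = list(barcode_source) if barcode_source is not None \
        else list(default_barcodes())
    report = check_collisions(
        pool, [rec.ungapped() for rec in alignment], n_needed=len(cols)
    )
    barcode_for_column = dict(zip(cols, report.selected))

    warnings: List[str] = []
    originals: Dict[Tuple[str, int], str] = {}
    out_records: List[SequenceRecord] = []
    for rec in alignment:
        chars = list(rec.residues)
        entries = []
        for col in cols:
            bc = barcode_for_column[col]
            orig = chars[col - 1]
            originals[(rec.id, col)] = orig
            entries.append((col, bc.id, orig))
            chars[col - 1] = bc.sequence
            if orig == GAP:
                warnings.append(
                    f"record {rec.id}: gap at barcoded column {col} "
                    "(barcode inserted, '-' stored)"
                )
            elif orig != "C":
                warnings.append(
                    f"record {rec.id}: non-cysteine residue {orig!r} "
                    f"at barcoded column {col}"
                )
        barcoded = "".join(chars).replace(GAP, "")
        header = encode_metadata(rec.id, BarcodeMetadata(entries))
        out_records.append(SequenceRecord(header, barcoded, rec.description))
    for msg in warnings:
        log.warning("%s", msg)

    assignment = BarcodeAssignment(
        columns=cols,
        barcode_for_column=barcode_for_column,
        originals=originals,
        warnings=warnings,
        collision_report=report,
    )
    return out_records, assignment


@dataclass
class SubgroupSpec:
    """One sub-group alignment with its columns and homology-class labels.

    ``labels[i]`` names the homology class anchored at ``columns[i]``; the
    same label in two sub-groups means "structurally the same cysteine"
    and receives the same barcode in both.
    """

    alignment: ProteinAlignment
    columns: Sequence[int]
    labels: Sequence[str]

    def __post_init__(self) -> None:
        if len(self.columns) != len(self.labels):
            raise MergeConflictError(
                "each barcoded column needs exactly one homology-class label"
            )


def barcode_subgroup_set(
    subgroups: Sequence[SubgroupSpec],
    barcode_source: Optional[Sequence[Barcode]] = None,
    barcode_for_label: Optional[Mapping[str, Barcode]] = None,
) -> Tuple[List[SequenceRecord], Dict[str, Barcode],
           List[BarcodeAssignment]]:
    """Barcode several sub-group alignments against a shared label→barcode
    map and pool the records for joint re-alignment.

    Homology-class labels are assigned barcodes in first-appearance order
    across the sub-groups (or from an explicit ``barcode_for_label`` map);
    a label bound to two different barcodes raises a merge conflict.
    Returns the pooled unaligned records, the label→barcode map, and one
    assignment ledger per sub-group.
    """
    pool = list(barcode_source) if barcode_source is not None \
        else list(default_barcodes())

    label_map: Dict[str, Barcode] = {}
    if barcode_for_label:
        for label, bc in barcode_for_label.items():
            if label in label_map and label_map[label].id != bc.id:
                raise MergeConflictError(
                    f"class {label!r} mapped to both "
                    f"{label_map[label].id} and {bc.id}"
                )
            label_map[label] = bc

    # collision-check the shared pool against every sub-group's sequences
    all_seqs = [rec.ungapped()
                for sg in subgroups for rec in sg.alignment]
    ordered_labels: List[str] = []
    for sg in subgroups:
        for label in sg.labels:
            if label not in ordered_labels:
                ordered_labels.append(label)
    unassigned = [lb for lb in ordered_labels if lb not in label_map]
    if unassigned:
        usable_pool = [bc for bc in pool
                       if bc.id not in {b.id for b in label_map.values()}]
        report = check_collisions(usable_pool, all_seqs,
                                  n_needed=len(unassigned))
        for label, bc in zip(unassigned, report.selected):
            label_map[label] = bc

    used_ids = [bc.id for bc in label_map.values()]
    if len(set(used_ids)) != len(used_ids):
        raise MergeConflictError(
            "two homology classes were mapped to the same barcode"
        )

    pooled: List[SequenceRecord] = []
    assignments: List[BarcodeAssignment] = []
    for sg in subgroups:
        # apply_barcodes consumes its pool in ascending column order, so
        # sort the (column, label) pairs together to keep the pairing
        pairs = sorted(zip(sg.columns, sg.labels))
        per_column = [label_map[lb] for _, lb in pairs]
        records, assignment = apply_barcodes(
            sg.alignment, [c for c, _ in pairs],
            barcode_source=per_column,
        )
        pooled.extend(records)
        assignments.append(assignment)
    return pooled, label_map, assignments
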