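"""Synthetic cysteine-rich protein families with known homology truth.

Real CRP families combine a conserved cysteine scaffold with highly
divergent inter-cysteine loops — low overall identity and frequent
indels, which is exactly what defeats naive aligners.  This generator
emulates that regime: an ancestor with ``n_cysteines`` scaffold cysteines
separated by random loops is evolved into descendants by per-residue loop
substitutions and per-loop indels, never touching the scaffold cysteines
(except through an explicit missing-cysteine rate, which gap-deletes
one).  Because every descendant's loops are built region by region, the
true alignment — and hence the true homology class of every scaffold
cysteine — is known by construction and returned alongside.

Loop residues deliberately exclude cysteine so the scaffold is exactly
the homology truth; see the methods note for what this simplification
does and does not exercise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .errors import InputMismatchError, ParameterError
from .seqio import GAP, ProteinAlignment, SequenceRecord
from .structure_columns import HomologyClass, HomologyClassSet, _roman

log = logging.getLogger(__name__)

# loop alphabet: the 20 amino acids minus cysteine, so scaffold cysteines
# are unambiguous ground truth
LOOP_ALPHABET = "ADEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilyConfig:
    """Study conditions for one synthetic family.

    Defaults emulate a divergent defensin-like sub-group: 20 sequences on
    a 6-cysteine scaffold, loops of 2–12 residues, 40 % per-residue loop
    substitution, one indel attempt per loop in half the loops.
    """

    n_sequences: int = 20
    n_cysteines: int = 6
    loop_length_range: Tuple[int, int] = (2, 12)
    substitution_rate: float = 0.4
    indel_rate: float = 0.5
    missing_cysteine_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.loop_length_range
        if lo > hi or lo < 0:
            raise ParameterError(
                f"loop_length_range {self.loop_length_range} is inverted"
            )
        for name in ("substitution_rate", "indel_rate",
                     "missing_cysteine_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.n_cysteines < 1:
            raise ParameterError("n_cysteines must be >= 1")
        if self.n_sequences < 2:
            raise ParameterError("n_sequences must be >= 2")


def _mutate_loop(loop: str, config: FamilyConfig,
                 rng: np.random.Generator) -> str:
    chars = list(loop)
    for i in range(len(chars)):
        if rng.random() < config.substitution_rate:
            chars[i] = LOOP_ALPHABET[rng.integers(len(LOOP_ALPHABET))]
    if chars and rng.random() < config.indel_rate:
        size = int(rng.integers(1, 4))  # 1-3 residues
        if rng.random() < 0.5 and len(chars) > size:  # deletion
            pos = int(rng.integers(0, len(chars) - size + 1))
            del chars[pos:pos + size]
        else:  # insertion
            pos = int(rng.integers(0, len(chars) + 1))
            ins = [LOOP_ALPHABET[rng.integers(len(LOOP_ALPHABET))]
                   for _ in range(size)]
            chars[pos:pos] = ins
    return "".join(chars)


def generate_family(config: FamilyConfig
                    ) -> Tuple[ProteinAlignment, HomologyClassSet]:
    """Generate one family; returns the true alignment and the true
    cysteine homology classes, reproducibly from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    k = config.n_cysteines
    lo, hi = config.loop_length_range
    ancestor_loops = [
        "".join(LOOP_ALPHABET[rng.integers(len(LOOP_ALPHABET))]
                for _ in range(int(rng.integers(lo, hi + 1))))
        for _ in range(k + 1)
    ]

    # descendants: per-region loop variants + cysteine presence flags
    variants: List[List[str]] = []   # [seq][region]
    has_cys: List[List[bool]] = []   # [seq][cysteine]
    for _ in range(config.n_sequences):
        variants.append(
            [_mutate_loop(loop, config, rng) for loop in ancestor_loops]
        )
        has_cys.append(
            [rng.random() >= config.missing_cysteine_rate for _ in range(k)]
        )

    # true alignment: each loop region padded right to its widest variant,
    # cysteines in single dedicated columns between regions
    widths = [max(len(variants[s][r]) for s in range(config.n_sequences))
              for r in range(k + 1)]
    records = []
    for s in range(config.n_sequences):
        parts = []
        for r in range(k + 1):
            loop = variants[s][r]
            parts.append(loop + GAP * (widths[r] - len(loop)))
            if r < k:
                parts.append("C" if has_cys[s][r] else GAP)
        records.append(SequenceRecord(f"seq{s + 1:03d}", "".join(parts)))
    alignment = ProteinAlignment(records)

    cys_columns = []
    col = 0
    for r in range(k):
        col += widths[r] + 1
        cys_columns.append(col)  # 1-based: widths sum + this cysteine
    classes = [
        HomologyClass(
            label=_roman(r + 1),
            members={(records[s].id, cys_columns[r])
                     for s in range(config.n_sequences) if has_cys[s][r]},
        )
        for r in range(k)
    ]
    return alignment, HomologyClassSet(classes=classes,
                                       provenance="user-confirmed")


def _ordinal_of_column(residues: str, column: int) -> int:
    """0-based residue ordinal of the character at 1-based ``column``."""
    if residues[column - 1] == GAP:
        raise InputMismatchError(
            f"column {column} holds a gap, not a residue"
        )
    return sum(1 for ch in residues[:column - 1] if ch != GAP)


def _column_of_ordinal(residues: str, ordinal: int) -> int:
    """1-based column of the ``ordinal``-th (0-based) residue."""
    seen = -1
    for i, ch in enumerate(residues):
        if ch != GAP:
            seen += 1
            if seen == ordinal:
                return i + 1
    raise InputMismatchError(f"sequence has fewer than {ordinal + 1} residues")


def misalignment_rate(
    test_alignment: ProteinAlignment,
    truth: HomologyClassSet,
    truth_alignment: ProteinAlignment,
) -> float:
    """Percentage of homology-class members not in their class's modal
    column of ``test_alignment``.

    Truth members are (record, column) pairs in truth-alignment
    coordinates; they are carried into the test alignment through residue
    ordinals (both alignments must contain the same gap-stripped
    sequences).  For each class, the most common test column is the modal
    column; members elsewhere count as misaligned.
    """
    test_records: Dict[str, SequenceRecord] = {
        rec.id: rec for rec in test_alignment
    }
    for rec in truth_alignment:
        if rec.id not in test_records:
            raise InputMismatchError(f"record {rec.id!r} missing from the "
                                     "test alignment")
        if test_records[rec.id].ungapped() != rec.ungapped():
            raise InputMismatchError(
                f"record {rec.id!r} differs between truth and test "
                "alignments (gap-stripped)"
            )
    total = 0
    misaligned = 0
    for cls in truth:
        columns: List[int] = []
        for rid, col in sorted(cls.members):
            ordinal = _ordinal_of_column(
                truth_alignment.record(rid).residues, col
            )
            columns.append(
                _column_of_ordinal(test_records[rid].residues, ordinal)
            )
        if not columns:
            continue
        modal = max(set(columns), key=lambda c: (columns.count(c), -c))
        misaligned += sum(1 for c in columns if c != modal)
        total += len(columns)
    if total == 0:
        raise InputMismatchError("truth contains no class members")
    return 100.0 * misaligned / total
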