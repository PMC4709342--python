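"""Suggest structurally homologous cysteine columns from a structure-based
alignment, and assign structureless sequences to sub-groups by similarity.

The upstream evidence is a backbone-based sequence alignment produced by a
structural-alignment service; in such an alignment two cysteines are taken
as structurally homologous when they sit in the same column or a
neighbouring one (a shift of less than ~3 Å along the backbone shows up as
at most one column of displacement).  Choosing which suggested classes to
barcode remains the user's decision — the suggestion is labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

from .errors import ParameterError
from .msa_lite import AlignParams, pairwise_score
from .seqio import ProteinAlignment, SequenceRecord


def _roman(n: int) -> str:
    numerals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"),
        (100, "C"), (90, "XC"), (50, "L"), (40, "XL"),
        (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass
class HomologyClass:
    """One set of structurally equivalent residue positions."""

    label: str
    members: Set[Tuple[str, int]]  # (record_id, 1-based column)

    @property
    def columns(self) -> List[int]:
        return sorted(col for _, col in self.members)


@dataclass
class HomologyClassSet:
    """Labelled homology classes with their provenance."""

    classes: List[HomologyClass]
    provenance: str = "suggested"

    def __post_init__(self) -> None:
        seen: Set[Tuple[str, int]] = set()
        for cls in self.classes:
            records = [rid for rid, _ in cls.members]
            if len(set(records)) != len(records):
                raise ParameterError(
                    f"class {cls.label}: a record contributes two columns"
                )
            overlap = seen & cls.members
            if overlap:
                raise ParameterError(
                    f"position {next(iter(overlap))} assigned to two classes"
                )
            seen |= cls.members

    def __iter__(self):
        return iter(self.classes)

    def __len__(self) -> int:
        return len(self.classes)

    def as_dict(self) -> Dict[str, List[str]]:
        return {
            cls.label: [f"{rid}:{col}" for rid, col in sorted(cls.members)]
            for cls in self.classes
        }


def suggest_homologous_cysteine_columns(
    structure_alignment: ProteinAlignment,
    neighbour_window: int = 1,
) -> HomologyClassSet:
    """Cluster cysteine positions of a structure-based alignment into
    suggested homology classes.

    Clustering is greedy and left-to-right: a class seeds at the leftmost
    unassigned cysteine column and absorbs, from each other record, its
    nearest unassigned cysteine within ``neighbour_window`` columns
    (nearer beats farther, left beats right on ties).  Classes are
    labelled with roman numerals in column order and marked "suggested" —
    confirming them is the user's decision.
    """
    if neighbour_window < 0:
        raise ParameterError("neighbour_window must be >= 0")
    positions: List[Tuple[int, str]] = []  # (column, record_id), column-sorted
    for rec in structure_alignment:
        for i, ch in enumerate(rec.residues):
            if ch == "C":
                positions.append((i + 1, rec.id))
    positions.sort(key=lambda p: (p[0], _record_order(structure_alignment,
                                                      p[1])))
    unassigned = set(positions)
    classes: List[HomologyClass] = []
    for seed_col, seed_rec in positions:
        if (seed_col, seed_rec) not in unassigned:
            continue
        members = {(seed_rec, seed_col)}
        unassigned.discard((seed_col, seed_rec))
        for rec in structure_alignment:
            if rec.id == seed_rec:
                continue
            candidates = [
                (col, rid) for (col, rid) in unassigned
                if rid == rec.id and abs(col - seed_col) <= neighbour_window
            ]
            if not candidates:
                continue
            best = min(candidates,
                       key=lambda p: (abs(p[0] - seed_col), p[0]))
            members.add((best[1], best[0]))
            unassigned.discard(best)
        classes.append(HomologyClass(label="", members=members))
    classes.sort(key=lambda c: min(col for _, col in c.members))
    for i, cls in enumerate(classes, 1):
        cls.label = _roman(i)
    return HomologyClassSet(classes=classes, provenance="suggested")


def _record_order(alignment: ProteinAlignment, record_id: str) -> int:
    for i, rec in enumerate(alignment):
        if rec.id == record_id:
            return i
    return len(alignment.records)


def assign_to_subgroup(
    query: SequenceRecord,
    representatives: Sequence[SequenceRecord],
    params: AlignParams = AlignParams(),
) -> Tuple[SequenceRecord, float]:
    """Assign a sequence without structure to the sub-group of its most
    similar representative, by global pairwise alignment score.

    Ties break by representative input order.  This is a self-contained
    similarity assignment; users who prefer an external search tool can
    rank representatives themselves and call the barcoding stage directly.
    """
    reps = list(representatives)
    if not reps:
        raise ParameterError("at least one representative is required")
    best = reps[0]
    best_score = pairwise_score(query.ungapped(), reps[0].ungapped(), params)
    for rep in reps[1:]:
        score = pairwise_score(query.ungapped(), rep.ungapped(), params)
        if score > best_score:
            best, best_score = rep, score
    return best, best_score
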