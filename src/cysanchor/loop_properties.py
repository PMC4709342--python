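"""Per-loop biophysical profiles: length, hydropathy and net charge.

In a cysteine-rich protein the segments between consecutive scaffold
cysteines ("inter-cysteine loops") carry most of the functional
diversity.  Once a final alignment with anchored cysteine columns exists,
each record can be cut at those columns into loops — including the N- and
C-terminal tails — and profiled:

* length in residues (gaps excluded);
* hydropathy: the mean Kyte–Doolittle value over the loop's residues
  (GRAVY-style mean by default so loops of different length compare;
  a sum is available);
* net charge at neutral pH: +1 per K/R, -1 per D/E, a configurable
  histidine contribution (0 by default), termini ignored because loops
  are internal fragments.

Profiles are written as a plain CSV (default name ``loop_statistics.csv``)
for downstream spreadsheet or dataframe analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .errors import ColumnRangeError, EmptyInputError, UnknownResidueError
from .seqio import GAP, ProteinAlignment

log = logging.getLogger(__name__)

#: Kyte–Doolittle hydropathy scale (positive = hydrophobic).
KYTE_DOOLITTLE: Dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Default per-residue charge at neutral pH (histidine configurable).
CHARGE: Dict[str, float] = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


@dataclass(frozen=True)
class LoopProfile:
    """Biophysical statistics of one loop of one record.

    ``loop_index`` 0 is the N-terminal tail; the last index is the
    C-terminal tail.  ``hydropathy`` is ``None`` for empty loops.
    """

    record_id: str
    loop_index: int
    length: int
    hydropathy: Optional[float]
    net_charge: float


def split_loops(
    alignment: ProteinAlignment,
    anchor_columns: Sequence[int],
) -> Dict[str, List[str]]:
    """Cut each record at its anchor columns into gap-stripped loops.

    Anchor residues are excluded from the loops; ``k`` anchors yield
    ``k + 1`` loops per record, counting both termini (which may be
    empty).
    """
    anchors = sorted(set(anchor_columns))
    for col in anchors:
        if not 1 <= col <= alignment.ncol:
            raise ColumnRangeError(
                f"anchor column {col} out of range 1..{alignment.ncol}"
            )
    bounds = [0] + anchors + [alignment.ncol + 1]
    loops: Dict[str, List[str]] = {}
    for rec in alignment:
        segs = []
        for lo, hi in zip(bounds, bounds[1:]):
            seg = rec.residues[lo: hi - 1]  # exclusive of both anchors
            segs.append(seg.replace(GAP, ""))
        loops[rec.id] = segs
    return loops


def hydropathy(
    loop: str,
    scale: Optional[Mapping[str, float]] = None,
    aggregate: str = "mean",
) -> Optional[float]:
    """Hydropathy of a gap-free loop under the given scale.

    Returns the mean (default) or sum of per-residue values; ``None`` for
    an empty loop.  A user-supplied scale table replaces the bundled
    Kyte–Doolittle values.
    """
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    table = KYTE_DOOLITTLE if scale is None else scale
    if not loop:
        return None
    values = []
    for ch in loop:
        if ch not in table:
            raise UnknownResidueError(
                f"residue {ch!r} absent from the hydropathy scale"
            )
        values.append(table[ch])
    total = sum(values)
    return total / len(values) if aggregate == "mean" else total


def net_charge(loop: str, histidine_charge: float = 0.0) -> float:
    """Signed charge of a loop at neutral pH (termini ignored).

    Unknown residues contribute zero and are logged, never fatal.
    """
    charge = 0.0
    for ch in loop:
        if ch in CHARGE:
            charge += CHARGE[ch]
        elif ch == "H":
            charge += histidine_charge
        elif ch not in KYTE_DOOLITTLE:
            log.info("residue %r has no charge assignment; counted as 0", ch)
    return charge


def profile_loops(
    alignment: ProteinAlignment,
    anchor_columns: Sequence[int],
    scale: Optional[Mapping[str, float]] = None,
    aggregate: str = "mean",
    histidine_charge: float = 0.0,
) -> List[LoopProfile]:
    """Profile every loop of every record of a final alignment."""
    loops = split_loops(alignment, anchor_columns)
    profiles = []
    for rec in alignment:
        for idx, loop in enumerate(loops[rec.id]):
            profiles.append(LoopProfile(
                record_id=rec.id,
                loop_index=idx,
                length=len(loop),
                hydropathy=hydropathy(loop, scale, aggregate),
                net_charge=net_charge(loop, histidine_charge),
            ))
    return profiles


def write_loop_csv(profiles: Sequence[LoopProfile], path) -> None:
    """Write profiles as CSV (header: record_id, loop_index, length,
    hydropathy, net_charge); empty-loop hydropathy serialises as ``NA``."""
    if not profiles:
        raise EmptyInputError("no loop profiles to write")
    frame = pd.DataFrame(
        [
            {
                "record_id": p.record_id,
                "loop_index": p.loop_index,
                "length": p.length,
                "hydropathy": p.hydropathy,
                "net_charge": p.net_charge,
            }
            for p in profiles
        ]
    )
    frame.to_csv(path, index=False, na_rep="NA")


def read_loop_csv(path) -> List[LoopProfile]:
    """Read back a CSV written by :func:`write_loop_csv`."""
    frame = pd.read_csv(path, na_values=["NA"])
    profiles = []
    for row in frame.itertuples(index=False):
        hyd = None if (isinstance(row.hydropathy, float)
                       and math.isnan(row.hydropathy)) else row.hydropathy
        profiles.append(LoopProfile(
            record_id=str(row.record_id),
            loop_index=int(row.loop_index),
            length=int(row.length),
            hydropathy=hyd,
            net_charge=float(row.net_charge),
        ))
    return profiles


def summarize_loops(profiles: Sequence[LoopProfile]) -> str:
    """Plain-text per-loop summary (count, length range, mean hydropathy
    and charge) for quick inspection without a spreadsheet."""
    frame = pd.DataFrame(
        [(p.loop_index, p.length, p.hydropathy, p.net_charge)
         for p in profiles],
        columns=["loop", "length", "hydropathy", "net_charge"],
    )
    grouped = frame.groupby("loop").agg(
        n=("length", "size"),
        len_min=("length", "min"),
        len_max=("length", "max"),
        len_mean=("length", "mean"),
        hyd_mean=("hydropathy", "mean"),
        charge_mean=("net_charge", "mean"),
    )
    lines = ["loop  n  len(min-max)  len_mean  hydropathy_mean  charge_mean"]
    for loop, row in grouped.iterrows():
        hyd = "NA" if pd.isna(row.hyd_mean) else f"{row.hyd_mean:+.2f}"
        lines.append(
            f"{loop:>4}  {int(row.n)}  {int(row.len_min)}-{int(row.len_max)}"
            f"  {row.len_mean:.1f}  {hyd}  {row.charge_mean:+.2f}"
        )
    return "\n".join(lines)
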