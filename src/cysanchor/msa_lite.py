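"""A minimal, deterministic global aligner for the barcode pipeline.

Barcoded sequences must be re-aligned before reconstruction; any standard
multiple aligner works, because the rare-residue barcodes dominate the
score and pin the anchored columns.  This module supplies a small
self-contained option — optimal global pairwise alignment under affine
gap scoring (Gotoh's algorithm) and a progressive sequence-to-profile
multiple aligner — so the whole round trip runs without external
binaries, plus an adapter for invoking an external aligner when one is
preferred.

Scoring conventions: substitution scores come from a named matrix
(BLOSUM62 by default, via Biopython's substitution-matrix collection);
a gap run of length L costs ``gap_open + (L - 1) * gap_extend``.
Tie-breaking in the traceback is fixed — on equal score a residue pair is
preferred over a gap in the first sequence, which is preferred over a gap
in the second — so results are fully deterministic.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, List, Optional, Sequence, Tuple

from Bio.Align import substitution_matrices

from .errors import AdapterError, EmptyInputError
from .seqio import (
    GAP,
    ProteinAlignment,
    SequenceRecord,
    read_alignment,
)

NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters: substitution matrix and affine gap penalties."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0 (they are subtracted)")


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


def substitution_score(a: str, b: str, params: AlignParams) -> float:
    m = _matrix(params.matrix)
    return float(m[a, b])


# DP states; also the traceback preference order on ties:
# residue pair beats gap-in-first beats gap-in-second.
_M, _GAP_IN_A, _GAP_IN_B = 0, 1, 2


def _affine_dp(
    m: int,
    n: int,
    pair_score: Callable[[int, int], float],
    params: AlignParams,
    traceback: bool = True,
):
    """Gotoh affine-gap global DP over an m x n problem.

    ``pair_score(i, j)`` scores pairing item i of the first axis with item
    j of the second (0-based).  Returns (score, path) where path is a list
    of states from the start, or (score, None) when traceback is False.
    """
    go, ge = params.gap_open, params.gap_extend
    # rows: state -> list of current-row scores
    M = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    A = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # gap in first axis
    B = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # gap in second axis
    M[0][0] = 0.0
    for j in range(1, n + 1):
        A[0][j] = -(go + (j - 1) * ge)
    for i in range(1, m + 1):
        B[i][0] = -(go + (i - 1) * ge)
    for i in range(1, m + 1):
        Mi, Ai, Bi = M[i], A[i], B[i]
        Mp, Ap, Bp = M[i - 1], A[i - 1], B[i - 1]
        for j in range(1, n + 1):
            s = pair_score(i - 1, j - 1)
            Mi[j] = s + max(Mp[j - 1], Ap[j - 1], Bp[j - 1])
            Ai[j] = max(Mi[j - 1] - go, Ai[j - 1] - ge, Bi[j - 1] - go)
            Bi[j] = max(Mp[j] - go, Bp[j] - ge, Ap[j] - go)
    end_scores = (M[m][n], A[m][n], B[m][n])
    score = max(end_scores)
    if not traceback:
        return score, None

    def _pick(prevs: Tuple[float, float, float], target: float) -> int:
        # exact float equality holds: all entries are sums of the same terms
        return min(k for k in range(3) if prevs[k] == target)

    state = end_scores.index(score)  # preference order on ties
    i, j = m, n
    path: List[int] = []
    while i > 0 or j > 0:
        path.append(state)
        if state == _M:
            # re-evaluate the forward expression (s + prev) so float
            # comparison is bitwise-exact
            s = pair_score(i - 1, j - 1)
            target = M[i][j]
            state = _pick(
                (s + M[i - 1][j - 1], s + A[i - 1][j - 1],
                 s + B[i - 1][j - 1]), target
            )
            i, j = i - 1, j - 1
        elif state == _GAP_IN_A:
            target = A[i][j]
            state = _pick(
                (M[i][j - 1] - go, A[i][j - 1] - ge, B[i][j - 1] - go),
                target,
            )
            j -= 1
        else:
            target = B[i][j]
            state = _pick(
                (M[i - 1][j] - go, A[i - 1][j] - go, B[i - 1][j] - ge),
                target,
            )
            i -= 1
    path.reverse()
    return score, path


def pairwise_align(
    a: str,
    b: str,
    params: Optional[AlignParams] = None,
) -> Tuple[str, str, float]:
    """Optimal global alignment of two gap-free sequences.

    Returns ``(aligned_a, aligned_b, score)``; the alignment is unique
    given the documented tie-break order.
    """
    if not a or not b:
        raise EmptyInputError("cannot align an empty sequence")
    params = params or AlignParams()
    mat = _matrix(params.matrix)

    def pair_score(i: int, j: int) -> float:
        return float(mat[a[i], b[j]])

    score, path = _affine_dp(len(a), len(b), pair_score, params)
    out_a, out_b = [], []
    i = j = 0
    for state in path:
        if state == _M:
            out_a.append(a[i]); out_b.append(b[j])
            i += 1; j += 1
        elif state == _GAP_IN_A:
            out_a.append(GAP); out_b.append(b[j])
            j += 1
        else:
            out_a.append(a[i]); out_b.append(GAP)
            i += 1
    return "".join(out_a), "".join(out_b), score


def pairwise_score(a: str, b: str, params: Optional[AlignParams] = None
                   ) -> float:
    """Optimal global alignment score only (no traceback)."""
    if not a or not b:
        raise EmptyInputError("cannot align an empty sequence")
    params = params or AlignParams()
    mat = _matrix(params.matrix)

    def pair_score(i: int, j: int) -> float:
        return float(mat[a[i], b[j]])

    score, _ = _affine_dp(len(a), len(b), pair_score, params,
                          traceback=False)
    return score


def _align_to_profile(
    rows: List[str],
    seq: str,
    params: AlignParams,
) -> Tuple[List[str], str]:
    """Align one sequence to an existing profile (list of aligned rows).

    A profile column scores a residue by the mean substitution score over
    the column's non-gap characters (gaps contribute zero), so conserved
    rare-residue barcode columns attract their counterparts strongly.
    """
    mat = _matrix(params.matrix)
    ncol = len(rows[0])
    nrows = len(rows)
    columns = ["".join(r[c] for r in rows) for c in range(ncol)]
    col_profiles = []
    for col in columns:
        residues = [ch for ch in col if ch != GAP]
        col_profiles.append(residues)

    def pair_score(i: int, j: int) -> float:
        residues = col_profiles[i]
        if not residues:
            return 0.0
        return sum(float(mat[ch, seq[j]]) for ch in residues) / nrows

    _, path = _affine_dp(ncol, len(seq), pair_score, params)
    new_rows = [[] for _ in rows]
    new_seq: List[str] = []
    i = j = 0
    for state in path:
        if state == _M:
            for k, r in enumerate(rows):
                new_rows[k].append(r[i])
            new_seq.append(seq[j])
            i += 1; j += 1
        elif state == _GAP_IN_A:  # gap inserted into the profile
            for nr in new_rows:
                nr.append(GAP)
            new_seq.append(seq[j])
            j += 1
        else:  # gap in the new sequence
            for k, r in enumerate(rows):
                new_rows[k].append(r[i])
            new_seq.append(GAP)
            i += 1
    return ["".join(r) for r in new_rows], "".join(new_seq)


def progressive_msa(
    records: Sequence[SequenceRecord],
    params: Optional[AlignParams] = None,
) -> ProteinAlignment:
    """Progressive multiple alignment of gap-free records.

    The two highest-scoring sequences are aligned first; remaining
    sequences join the growing profile in single-linkage order (the
    unaligned sequence with the best pairwise score to any aligned one is
    added next, ties broken by input order).  Deterministic for a fixed
    input order.
    """
    params = params or AlignParams()
    records = list(records)
    if len(records) == 1:
        raise EmptyInputError(
            "progressive_msa needs at least 2 records (single record is "
            "already trivially aligned)"
        )
    seqs = [rec.ungapped() for rec in records]
    n = len(seqs)

    scores = {}
    for i in range(n):
        for j in range(i + 1, n):
            scores[(i, j)] = pairwise_score(seqs[i], seqs[j], params)

    def pair_key(i: int, j: int) -> float:
        return scores[(min(i, j), max(i, j))]

    first = max(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda p: (pair_key(*p), -p[0], -p[1]),
    )
    a, b, _ = pairwise_align(seqs[first[0]], seqs[first[1]], params)
    member_order = [first[0], first[1]]
    rows = [a, b]
    remaining = [k for k in range(n) if k not in member_order]
    while remaining:
        nxt = max(
            remaining,
            key=lambda k: (max(pair_key(k, m) for m in member_order), -k),
        )
        rows, new_row = _align_to_profile(rows, seqs[nxt], params)
        rows.append(new_row)
        member_order.append(nxt)
        remaining.remove(nxt)

    row_of = {member: row for member, row in zip(member_order, rows)}
    out = [
        SequenceRecord(records[k].id, row_of[k], records[k].description)
        for k in range(n)
    ]
    return ProteinAlignment(out)


def external_aligner_adapter(
    fasta_in: str,
    command_template: str,
    fasta_out: Optional[str] = None,
) -> str:
    """Re-align a FASTA file with a user-supplied external aligner.

    ``command_template`` must contain ``{in}`` and ``{out}`` placeholders,
    e.g. ``"mafft --auto {in} > {out}"``.  The output is validated: it
    must be a well-formed alignment containing exactly the input record
    ids with unchanged (gap-stripped) residues.  Returns the output path.
    """
    if "{in}" not in command_template or "{out}" not in command_template:
        raise AdapterError(
            "command template must contain {in} and {out} placeholders"
        )
    from .seqio import read_fasta
    in_records = read_fasta(fasta_in)
    if fasta_out is None:
        fasta_out = tempfile.mkstemp(suffix=".fasta")[1]
    cmd = command_template.replace("{in}", shlex.quote(fasta_in)) \
                          .replace("{out}", shlex.quote(fasta_out))
    proc = subprocess.run(
        cmd, shell=True, capture_output=True, text=True,
    )
    if proc.returncode != 0:
        raise AdapterError(
            f"external aligner failed (exit {proc.returncode}): "
            f"{proc.stderr.strip()[:500]}"
        )
    try:
        out_aln = read_alignment(fasta_out)
    except Exception as exc:
        raise AdapterError(f"external aligner output is not a valid "
                           f"alignment: {exc}") from exc
    in_ids = {r.id for r in in_records}
    out_ids = {r.id for r in out_aln}
    if in_ids != out_ids:
        lost = sorted(in_ids - out_ids)
        raise AdapterError(f"aligner output lost records: {lost}")
    in_res = {r.id: r.ungapped() for r in in_records}
    for rec in out_aln:
        if rec.ungapped() != in_res[rec.id]:
            raise AdapterError(
                f"aligner altered residues of record {rec.id!r}"
            )
    return fasta_out
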