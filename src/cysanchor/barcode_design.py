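"""Design and vetting of peptide barcodes.

A barcode is a short peptide tag built from the rarest amino acids
(tryptophan, histidine, methionine, tyrosine by default) that is inserted
in place of a structurally homologous cysteine column so that any aligner
is forced to keep those columns together.  A usable barcode set must

* be high-complexity (composition Shannon entropy above a threshold), so
  no barcode looks like low-complexity sequence;
* keep every pair of barcodes at least ``distance_min`` substitutions or
  indels apart (unit-cost edit distance, called Hamming+ here), so
  barcodes cannot erroneously align to one another; and
* be vanishingly unlikely to occur by chance in real sequence, which the
  rare-residue alphabet guarantees (P(match) ~ 1e-10 even for a thousand
  sequences of length one thousand).

Barcodes are additionally checked against the user's actual sequences for
exact substring collisions, and colliding barcodes are replaced by the
next barcode in rank order.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import (
    EmptyInputError,
    InsufficientBarcodesError,
    LengthMismatchError,
    UnknownResidueError,
)

log = logging.getLogger(__name__)

try:  # fast unit-cost edit distance; pure-DP fallback below
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover - edlib is a declared dependency
    _HAVE_EDLIB = False

#: Average amino-acid composition of known proteins (relative frequency),
#: as tabulated by the ExPASy protein-identification tools (Wilkins et al.).
#: Used as the background model for chance-match probabilities.
AVERAGE_AA_FREQUENCIES: Dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

#: The first eight barcodes of the published default set, used as reference
#: sequences in validation: length 10, alphabet {W,H,M,Y}, pairwise
#: substitution distance >= 7.
REFERENCE_BARCODES: Tuple[str, ...] = (
    "WWYHWYYHMM",  # bc.001
    "WHWMMHYHYY",  # bc.002
    "WWHHMWMMYW",  # bc.003
    "WHYYMMWMWM",  # bc.004
    "HWWMYHHMHW",  # bc.005
    "HMHYYWHHYM",  # bc.006
    "MMYMWMWHHW",  # bc.007
    "MYYHHMYWYY",  # bc.008
)


@dataclass(frozen=True)
class Barcode:
    """A ranked peptide barcode with its design statistics."""

    id: str
    sequence: str
    entropy_bits: float
    min_distance_to_set: int


@dataclass(frozen=True)
class BarcodeDesignConfig:
    """Parameters of the barcode generator.

    ``alphabet`` defaults to the four least common amino acids; ``length``
    to ten residues; ``entropy_min`` (bits) and ``distance_min`` (edits)
    are the complexity and separation thresholds; ``count`` is the number
    of barcodes requested.
    """

    alphabet: Tuple[str, ...] = ("H", "M", "W", "Y")
    length: int = 10
    entropy_min: float = 1.8
    distance_min: int = 4
    count: int = 949
    background_freqs: Tuple[Tuple[str, float], ...] = field(
        default_factory=lambda: tuple(sorted(AVERAGE_AA_FREQUENCIES.items()))
    )

    def __post_init__(self) -> None:
        if len(set(self.alphabet)) < 2:
            raise ValueError("alphabet must contain at least 2 residues")
        if self.entropy_min < 0:
            raise ValueError("entropy_min must be >= 0")
        if self.distance_min < 1:
            raise ValueError("distance_min must be >= 1")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        object.__setattr__(self, "alphabet", tuple(sorted(set(self.alphabet))))
        # stored as a sorted tuple of pairs so configs stay hashable
        object.__setattr__(
            self, "background_freqs",
            tuple(sorted(dict(self.background_freqs).items())),
        )

    @property
    def frequencies(self) -> Dict[str, float]:
        return dict(self.background_freqs)


@dataclass(frozen=True)
class MatchRisk:
    """Chance-match probability of a barcode against random sequence."""

    per_window_probability: float
    total_probability: float
    n_sequences: int
    sequence_length: int
    n_windows: int


def shannon_entropy(sequence: str) -> float:
    """Composition Shannon entropy H = -sum p_a log2 p_a, in bits."""
    if not sequence:
        raise EmptyInputError("cannot compute entropy of an empty sequence")
    n = len(sequence)
    counts: Dict[str, int] = {}
    for ch in sequence:
        counts[ch] = counts.get(ch, 0) + 1
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def hamming(a: str, b: str) -> int:
    """Substitution-only distance between equal-length strings."""
    if len(a) != len(b):
        raise LengthMismatchError(
            f"hamming needs equal lengths, got {len(a)} and {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


def _edit_distance_dp(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance by dynamic programming."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def hamming_plus(a: str, b: str) -> int:
    """Minimum number of substitutions plus indels turning ``a`` into ``b``
    (unit-cost edit distance).  For equal lengths this is <= hamming(a, b)."""
    if _HAVE_EDLIB:
        if not a or not b:
            return abs(len(a) - len(b))
        return edlib.align(a, b)["editDistance"]
    return _edit_distance_dp(a, b)


def _distance_at_least(a: str, b: str, d: int) -> bool:
    """True iff hamming_plus(a, b) >= d; uses edlib's banded search."""
    if _HAVE_EDLIB and a and b:
        return edlib.align(a, b, k=d - 1)["editDistance"] == -1
    return hamming_plus(a, b) >= d


def match_probability(
    barcode: str,
    n_sequences: int,
    sequence_length: int,
    background_freqs: Optional[Mapping[str, float]] = None,
) -> MatchRisk:
    """Probability that ``barcode`` occurs by chance in an alignment of
    ``n_sequences`` random sequences of ``sequence_length`` residues.

    The per-window probability is the product of the background
    frequencies of the barcode's residues; the total multiplies by the
    number of length-``len(barcode)`` windows in the alignment.
    """
    freqs = AVERAGE_AA_FREQUENCIES if background_freqs is None else background_freqs
    per_window = 1.0
    for ch in barcode:
        if ch not in freqs:
            raise UnknownResidueError(
                f"residue {ch!r} missing from the background frequency table"
            )
        per_window *= freqs[ch]
    n_windows = n_sequences * max(0, sequence_length - len(barcode) + 1)
    return MatchRisk(
        per_window_probability=per_window,
        total_probability=per_window * n_windows,
        n_sequences=n_sequences,
        sequence_length=sequence_length,
        n_windows=n_windows,
    )


def _admit_candidates(config: BarcodeDesignConfig) -> List[str]:
    """Greedy lexicographic scan admitting candidates that keep the set's
    pairwise Hamming+ distance >= distance_min."""
    admitted: List[str] = []
    for chars in itertools.product(config.alphabet, repeat=config.length):
        seq = "".join(chars)
        if shannon_entropy(seq) < config.entropy_min:
            continue
        if all(_distance_at_least(seq, other, config.distance_min)
               for other in admitted):
            admitted.append(seq)
            if len(admitted) >= config.count:
                break
    return admitted


def generate_default_barcodes(config: Optional[BarcodeDesignConfig] = None
                              ) -> List[Barcode]:
    """Deterministically generate the ranked default barcode set.

    Candidates are enumerated lexicographically over
    ``alphabet ** length``, filtered by the entropy threshold, and
    admitted greedily subject to the pairwise distance threshold.  The
    admitted set is then ranked by robustness (minimum distance to the
    rest of the set, descending), breaking ties by complexity (entropy,
    descending) and finally lexicographically; ids ``bc.001`` onward
    follow that final order.

    If the candidate pool is exhausted before ``count`` barcodes are
    admitted a warning is logged and the shorter list returned.
    """
    config = config or BarcodeDesignConfig()
    admitted = _admit_candidates(config)
    if len(admitted) < config.count:
        log.warning(
            "barcode pool exhausted: %d of %d requested barcodes generated",
            len(admitted), config.count,
        )
    if len(admitted) == 1:
        min_dists = [config.length]
    else:
        min_dists = [
            min(hamming_plus(seq, other)
                for other in admitted if other is not seq)
            for seq in admitted
        ]
    ranked = sorted(
        zip(admitted, min_dists),
        key=lambda item: (-item[1], -shannon_entropy(item[0]), item[0]),
    )
    return [
        Barcode(
            id=f"bc.{i:03d}",
            sequence=seq,
            entropy_bits=shannon_entropy(seq),
            min_distance_to_set=dist,
        )
        for i, (seq, dist) in enumerate(ranked, 1)
    ]


#: Size of the cached canonical pool used when a caller supplies no pool.
#: 100 barcodes cover far more anchored columns than any real scaffold has,
#: and the truncated pool generates in about a second.
DEFAULT_POOL_COUNT = 100


@lru_cache(maxsize=4)
def _cached_default_barcodes(config: BarcodeDesignConfig) -> Tuple[Barcode, ...]:
    return tuple(generate_default_barcodes(config))


def default_barcodes(config: Optional[BarcodeDesignConfig] = None
                     ) -> Tuple[Barcode, ...]:
    """The canonical default barcode pool (cached).

    Barcode ids are deterministic for a fixed config, so the pool used at
    barcoding time can be re-derived at reconstruction time without
    shipping the sequences alongside the FASTA file.
    """
    return _cached_default_barcodes(
        config or BarcodeDesignConfig(count=DEFAULT_POOL_COUNT)
    )


@dataclass(frozen=True)
class Substitution:
    """One entry of a collision report."""

    requested: str  # barcode id that would have been used
    used: str       # barcode id actually used
    reason: str


@dataclass
class CollisionReport:
    """Outcome of selecting collision-free barcodes from a ranked pool."""

    selected: List[Barcode]
    substitutions: List[Substitution]

    @property
    def had_collisions(self) -> bool:
        return any(s.requested != s.used for s in self.substitutions)


def check_collisions(
    barcodes: Sequence[Barcode],
    sequences: Iterable[str],
    n_needed: Optional[int] = None,
) -> CollisionReport:
    """Select the first ``n_needed`` barcodes from the ranked pool whose
    sequences do not occur as exact substrings of any input sequence.

    Input sequences are gap-stripped before matching.  A colliding barcode
    is skipped and the next barcode in rank order substituted; the report
    records every substitution so the user can see which barcodes were
    actually used.
    """
    if n_needed is None:
        n_needed = len(barcodes)
    stripped = [s.replace("-", "").upper() for s in sequences]
    colliders = []
    clean: List[Barcode] = []
    for bc in barcodes:
        if any(bc.sequence in s for s in stripped):
            colliders.append(bc)
            log.warning(
                "barcode %s (%s) occurs in an input sequence; the next "
                "suitable barcode will be used instead", bc.id, bc.sequence,
            )
        else:
            clean.append(bc)
        if len(clean) >= n_needed:
            break
    if len(clean) < n_needed:
        raise InsufficientBarcodesError(
            f"only {len(clean)} collision-free barcodes available, "
            f"{n_needed} needed"
        )
    selected = clean[:n_needed]
    collider_ids = {bc.id for bc in colliders}
    substitutions = []
    for req, used in zip(barcodes, selected):
        if req.id == used.id:
            reason = "no collision"
        elif req.id in collider_ids:
            reason = f"{req.id} ({req.sequence}) collides with an input sequence"
        else:
            reason = "shifted by an earlier collision"
        substitutions.append(Substitution(req.id, used.id, reason))
    return CollisionReport(selected=selected, substitutions=substitutions)
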