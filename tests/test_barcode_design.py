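"""Barcode generation, distances, entropy and collision handling."""

import itertools
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cysanchor.barcode_design import (
    AVERAGE_AA_FREQUENCIES,
    BarcodeDesignConfig,
    REFERENCE_BARCODES,
    check_collisions,
    generate_default_barcodes,
    hamming,
    hamming_plus,
    match_probability,
    shannon_entropy,
)
from cysanchor.errors import (
    EmptyInputError,
    InsufficientBarcodesError,
    LengthMismatchError,
    UnknownResidueError,
)
from .conftest import make_barcode


def brute_force_edit_distance(a: str, b: str, _memo=None) -> int:
    """Independent oracle: recursive unit-cost edit distance (memoised)."""
    if _memo is None:
        _memo = {}
    if (a, b) in _memo:
        return _memo[(a, b)]
    if not a:
        result = len(b)
    elif not b:
        result = len(a)
    else:
        result = min(
            brute_force_edit_distance(a[1:], b[1:], _memo) + (a[0] != b[0]),
            brute_force_edit_distance(a[1:], b, _memo) + 1,
            brute_force_edit_distance(a, b[1:], _memo) + 1,
        )
    _memo[(a, b)] = result
    return result


class TestShannonEntropy:
    def test_reference_barcode_composition(self):
        # composition (3,3,2,2)/10, hand-evaluated -sum p log2 p
        assert shannon_entropy("WWYHWYYHMM") == pytest.approx(1.971, abs=1e-3)

    def test_single_letter_is_zero(self):
        assert shannon_entropy("AAAAAAAAAA") == 0.0

    def test_skewed_composition(self):
        # composition (5,2,2,1)/10
        assert shannon_entropy("MYYHHMYWYY") == pytest.approx(1.761, abs=1e-3)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            shannon_entropy("")


class TestHamming:
    @pytest.mark.parametrize("a,b,expected", [
        ("WWYHWYYHMM", "WHWMMHYHYY", 7),
        ("WHMY", "WHMY", 0),
        ("WWHHMWMMYW", "MMYMWMWHHW", 9),
    ])
    def test_position_wise(self, a, b, expected):
        assert hamming(a, b) == expected

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatchError):
            hamming("AA", "AAA")


class TestHammingPlus:
    @pytest.mark.parametrize("a,b,expected", [
        ("AAA", "AAA", 0),
        ("AAAA", "AAA", 1),
        ("", "ABC", 3),
    ])
    def test_simple_cases(self, a, b, expected):
        assert hamming_plus(a, b) == expected

    def test_reference_pair_against_oracle(self):
        a, b = "WWYHWYYHMM", "WHWMMHYHYY"
        d = hamming_plus(a, b)
        assert d == brute_force_edit_distance(a, b)
        assert d <= 7

    def test_exhaustive_against_oracle_short_binary_strings(self):
        """hamming_plus equals the brute-force oracle on every pair of
        strings of length <= 5 over a 2-letter alphabet."""
        strings = [
            "".join(t)
            for n in range(4)
            for t in itertools.product("WY", repeat=n)
        ] + ["".join(t) for t in itertools.product("WY", repeat=5)]
        for a in strings:
            for b in strings:
                assert hamming_plus(a, b) == brute_force_edit_distance(a, b)

    @given(st.text(alphabet="HMWY", min_size=0, max_size=8),
           st.text(alphabet="HMWY", min_size=0, max_size=8),
           st.text(alphabet="HMWY", min_size=0, max_size=8))
    def test_metric_properties(self, a, b, c):
        assert hamming_plus(a, b) == hamming_plus(b, a)
        assert (hamming_plus(a, b) == 0) == (a == b)
        assert hamming_plus(a, c) <= hamming_plus(a, b) + hamming_plus(b, c)

    @given(st.integers(min_value=1, max_value=8).flatmap(
        lambda n: st.tuples(st.text(alphabet="HMWY", min_size=n, max_size=n),
                            st.text(alphabet="HMWY", min_size=n, max_size=n))
    ))
    def test_bounded_by_hamming_for_equal_lengths(self, pair):
        a, b = pair
        assert hamming_plus(a, b) <= hamming(a, b)


class TestMatchProbability:
    def test_closed_form_single_window(self):
        risk = match_probability("W" * 10, n_sequences=1, sequence_length=10,
                                 background_freqs={"W": 0.011})
        assert risk.n_windows == 1
        assert risk.per_window_probability == pytest.approx(0.011 ** 10)
        assert risk.total_probability == pytest.approx(2.59e-21, rel=0.01)

    def test_no_windows_when_sequences_too_short(self):
        risk = match_probability("WWYHWYYHMM", n_sequences=5,
                                 sequence_length=4)
        assert risk.n_windows == 0 and risk.total_probability == 0.0

    def test_reference_barcode_large_alignment_bound(self):
        """The most easily matched reference barcode stays below the
        1e-10 chance-match bound for 1000 sequences of length 1000."""
        risk = match_probability("MYYHHMYWYY", n_sequences=1000,
                                 sequence_length=1000)
        assert risk.total_probability == pytest.approx(7e-11, rel=0.05)
        assert risk.total_probability <= 1e-10

    def test_unknown_residue(self):
        with pytest.raises(UnknownResidueError):
            match_probability("WZ", 1, 10)

    def test_linear_in_n_sequences(self):
        r1 = match_probability("WWYH", 10, 50)
        r2 = match_probability("WWYH", 30, 50)
        assert r2.total_probability == pytest.approx(
            3 * r1.total_probability)

    def test_monotone_under_rarer_residue_swap(self):
        # W is the rarest residue in the background table
        common = match_probability("LWYH", 10, 50).total_probability
        rare = match_probability("WWYH", 10, 50).total_probability
        assert rare < common


class TestGenerateDefaultBarcodes:
    def test_single_barcode_contract(self):
        (bc,) = generate_default_barcodes(BarcodeDesignConfig(count=1))
        assert bc.id == "bc.001"
        assert len(bc.sequence) == 10
        assert set(bc.sequence) <= {"W", "H", "M", "Y"}

    def test_count8_pairwise_properties(self):
        config = BarcodeDesignConfig(count=8)
        barcodes = generate_default_barcodes(config)
        assert len(barcodes) == 8
        for a, b in itertools.combinations(barcodes, 2):
            assert hamming_plus(a.sequence, b.sequence) >= config.distance_min
        assert all(b.entropy_bits >= config.entropy_min for b in barcodes)

    def test_distance_exceeding_length_exhausts_pool(self):
        barcodes = generate_default_barcodes(
            BarcodeDesignConfig(distance_min=11, length=10, count=5)
        )
        assert len(barcodes) <= 1

    def test_deterministic(self):
        config = BarcodeDesignConfig(count=12)
        first = generate_default_barcodes(config)
        second = generate_default_barcodes(config)
        assert first == second

    def test_ranking_orders_by_robustness_then_entropy(self):
        barcodes = generate_default_barcodes(BarcodeDesignConfig(count=20))
        keys = [(-b.min_distance_to_set, -b.entropy_bits, b.sequence)
                for b in barcodes]
        assert keys == sorted(keys)
        assert [b.id for b in barcodes] == \
            [f"bc.{i:03d}" for i in range(1, 21)]


class TestReferenceBarcodeSet:
    def test_lengths_and_alphabet(self):
        assert all(len(s) == 10 for s in REFERENCE_BARCODES)
        assert set("".join(REFERENCE_BARCODES)) == {"W", "H", "M", "Y"}

    def test_min_pairwise_substitution_distance(self):
        dmin = min(hamming(a, b)
                   for a, b in itertools.combinations(REFERENCE_BARCODES, 2))
        assert dmin == 7


class TestCheckCollisions:
    def test_collision_substitutes_next_barcode(self, small_pool):
        report = check_collisions(
            small_pool, ["AAAWWYHWYYHMMAAA"], n_needed=1
        )
        assert [bc.id for bc in report.selected] == ["bc.002"]
        assert report.substitutions[0].requested == "bc.001"
        assert report.substitutions[0].used == "bc.002"
        assert "collide" in report.substitutions[0].reason

    def test_no_collisions_identity_mapping(self, small_pool):
        report = check_collisions(small_pool, ["ACDEFG"], n_needed=3)
        assert [bc.id for bc in report.selected] == \
            ["bc.001", "bc.002", "bc.003"]
        assert all(s.requested == s.used for s in report.substitutions)

    def test_gaps_stripped_before_matching(self, small_pool):
        report = check_collisions(
            small_pool, ["WWYHW--YYHMM"], n_needed=1
        )
        assert report.selected[0].id == "bc.002"

    def test_exhaustion_raises(self, small_pool):
        pool = small_pool[:1]
        with pytest.raises(InsufficientBarcodesError):
            check_collisions(pool, ["WWYHWYYHMM"], n_needed=1)
        with pytest.raises(InsufficientBarcodesError):
            check_collisions(small_pool[:2], ["WWYHWYYHMM"], n_needed=2)
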