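import pytest
from hypothesis import HealthCheck, settings

from cysanchor.barcode_design import Barcode, shannon_entropy
from cysanchor.seqio import ProteinAlignment, SequenceRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_barcode(bcid: str, sequence: str) -> Barcode:
    return Barcode(
        id=bcid,
        sequence=sequence,
        entropy_bits=shannon_entropy(sequence),
        min_distance_to_set=0,
    )


@pytest.fixture
def toy_alignment() -> ProteinAlignment:
    """Three short defensin-like sequences with two shared cysteine
    columns (4 and 8) and divergent loops."""
    return ProteinAlignment([
        SequenceRecord("d1", "AKRC-GDCVL"),
        SequenceRecord("d2", "TP-CWGECI-"),
        SequenceRecord("d3", "GGACA--CKE"),
    ])


@pytest.fixture
def small_pool():
    """A tiny hand-built pool of well-separated rare-residue barcodes
    (the first entries of the published default set)."""
    return [
        make_barcode("bc.001", "WWYHWYYHMM"),
        make_barcode("bc.002", "WHWMMHYHYY"),
        make_barcode("bc.003", "WWHHMWMMYW"),
        make_barcode("bc.004", "WHYYMMWMWM"),
        make_barcode("bc.005", "HWWMYHHMHW"),
        make_barcode("bc.006", "HMHYYWHHYM"),
        make_barcode("bc.007", "MMYMWMWHHW"),
        make_barcode("bc.008", "MYYHHMYWYY"),
    ]
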