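import numpy as np
import pytest

from allerprofile import conservation as cons
from allerprofile import synthetic as syn


@pytest.fixture(scope="session")
def blosum62() -> cons.SubstitutionMatrix:
    return cons.load_substitution_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def species_tree():
    return syn.default_species_tree()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250926)


@pytest.fixture()
def toy_alignment() -> cons.AlignmentBlock:
    """Six-row gapped alignment with a clear majority in most columns."""
    return cons.AlignmentBlock(
        ["CF", "PP", "SP", "CO", "ES", "PC"],
        [
            "MKT-LIVE",
            "MKT-LIVE",
            "MKT-LIVE",
            "MRT-LIVE",
            "MRTALIVE",
            "MRSALICE",
        ],
    )
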