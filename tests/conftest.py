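import pytest

import amylpot as ap
from amylpot import Label, PeptideDataset, PeptideRecord


@pytest.fixture(scope="session")
def amy_matrix():
    return ap.load_amyloid_potentials()


@pytest.fixture(scope="session")
def non_matrix():
    return ap.load_non_amyloid_potentials()


@pytest.fixture(scope="session")
def ref_comp():
    return ap.load_reference_composition()


@pytest.fixture(scope="session")
def mant_scale():
    return ap.load_mant_scale()


@pytest.fixture()
def two_class_dataset():
    """Minimal labeled dataset: one amyloid, one non-amyloid hexapeptide."""
    return PeptideDataset.from_records(
        [
            PeptideRecord("stviie", "STVIIE", Label.AMYLOID),
            PeptideRecord("vqivyk", "VQIVYK", Label.NON_AMYLOID),
        ]
    )
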