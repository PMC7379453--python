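import pytest

from prolamap.motifmap import MotifPanel
from prolamap.synthetic import generate, toy_glupro_spec


@pytest.fixture(scope="session")
def toy_dataset():
    """The default synthetic fixture: 6 groups, 30 clean records, 25-motif
    panel, 3 duplicate + 2 ambiguous + 2 partial corrupted records, seed 1."""
    return generate(toy_glupro_spec(seed=1))


@pytest.fixture()
def worked_panel():
    """The hand-worked nested-fragment panel."""
    return MotifPanel(["PFPQ", "QQPFPQ", "QQQQ"])


WORKED_SEQUENCE = "QQPFPQQPQQPFPQ"


@pytest.fixture()
def worked_sequence():
    return WORKED_SEQUENCE
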