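import numpy as np
import pytest

from rbmdesign.msa_io import Alignment
from rbmdesign.synthetic_data import make_tiny_fixture


@pytest.fixture(scope="session")
def tiny():
    """Canonical enumerable fixture: (PlantedModel, Alignment, labels)."""
    return make_tiny_fixture()


@pytest.fixture(scope="session")
def tiny_model(tiny):
    return tiny[0]


@pytest.fixture(scope="session")
def tiny_aln(tiny):
    return tiny[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_alignment(rows, alphabet="ABC", ids=None):
    rows = np.asarray(rows)
    if ids is None:
        ids = [f"s{i}" for i in range(rows.shape[0])]
    return Alignment(ids=ids, rows=rows, alphabet=alphabet)
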