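import numpy as np
import pytest

from targetiso import (default_barcode_set, make_human_fixture,
                       make_mouse_fixture, make_toy_model)
from targetiso.simulate import simulate_per_isoform

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def mouse_model():
    return make_mouse_fixture(FIXTURE_SEED)


@pytest.fixture(scope="session")
def human_model():
    return make_human_fixture(FIXTURE_SEED)


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model(11, n_exons=3)


@pytest.fixture(scope="session")
def barcodes():
    return default_barcode_set()


@pytest.fixture(scope="session")
def mouse_catalog_reads(mouse_model, barcodes):
    """Small error-free library: 3 reads per mouse catalog isoform."""
    return simulate_per_isoform(mouse_model, barcodes, 3, seed=1000,
                                sub_rate=0, ins_rate=0, del_rate=0)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
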