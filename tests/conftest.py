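import numpy as np
import pytest
from hypothesis import settings

from randgene import DegenerateScheme, LibraryConfig, generate_library

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def nnb():
    return DegenerateScheme("NNB", "NNB", n_codons=50)


@pytest.fixture(scope="session")
def nyn():
    return DegenerateScheme("NYN", "NYN", n_codons=50)


@pytest.fixture(scope="session")
def small_library(nnb):
    cfg = LibraryConfig(scheme=nnb, n_variants=200, indel_rate=0.05, seed=11)
    return generate_library(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
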