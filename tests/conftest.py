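import numpy as np
import pytest

from diazoscan.recruit import AlignerParams
from diazoscan.synthgen import ReferencePanel


@pytest.fixture(scope="session")
def panel() -> ReferencePanel:
    return ReferencePanel(seed=11)


@pytest.fixture(scope="session")
def params() -> AlignerParams:
    return AlignerParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))
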