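import numpy as np
import pytest

from tetrack import synth


@pytest.fixture(scope="session")
def element() -> synth.TEElement:
    """One fixed synthetic element (23 bp TIRs, 492 aa transposase)."""
    return synth.make_te_element(5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_dna(n: int, seed: int) -> str:
    return synth.random_sequence(n, np.random.default_rng(seed))
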