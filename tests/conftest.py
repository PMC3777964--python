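import numpy as np
import pytest

from prfkit.fixtures import reporter_inserts, yip3_character_tree


@pytest.fixture(scope="session")
def inserts():
    return reporter_inserts()


@pytest.fixture(scope="session")
def podo1(inserts):
    return inserts["Podo-1"]


@pytest.fixture(scope="session")
def yip3_tree():
    return yip3_character_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(20130917)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
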