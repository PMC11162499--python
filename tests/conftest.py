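import numpy as np
import pytest

from gbekit.editors import builtin_editors


@pytest.fixture(scope="session")
def registry():
    return builtin_editors()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240608)


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
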