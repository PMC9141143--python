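import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scsopt as S

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def dna():
    return S.DNA


@pytest.fixture
def fig_alphabet():
    # the (a, c, t, g) ordering used by the worked encoding example
    return S.Alphabet.from_string("actg")


@pytest.fixture
def two_string_instance(dna):
    # strings "ac" and "ca"; optimum supersequence length is 3
    return S.Instance([[0, 1], [1, 0]], dna)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
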