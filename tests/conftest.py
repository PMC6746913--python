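import numpy as np
import pytest

from sixma.seqio import SampleWindow
from sixma.synthetic import SyntheticSpec, generate

BASES = "ACGT"


def random_window(rng: np.random.Generator, length: int = 41, label=None) -> SampleWindow:
    """A uniformly random valid window (central A enforced)."""
    chars = [BASES[i] for i in rng.integers(0, 4, size=length)]
    chars[(length - 1) // 2] = "A"
    return SampleWindow(id=f"r{rng.integers(1 << 30)}", seq="".join(chars), label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def window41(rng):
    return random_window(rng)


@pytest.fixture(scope="session")
def biased_fixture():
    """1,000 + 1,000 windows with strong positional bias (separable)."""
    return generate(SyntheticSpec(n_pos=1000, n_neg=1000, bias_strength=0.8, seed=7))


@pytest.fixture(scope="session")
def null_fixture():
    """1,000 + 1,000 windows with no class signal."""
    return generate(SyntheticSpec(n_pos=1000, n_neg=1000, bias_strength=0.0, seed=7))


@pytest.fixture(scope="session")
def small_biased_fixture():
    """A fast 100 + 100 separable fixture for protocol-level tests."""
    return generate(SyntheticSpec(n_pos=100, n_neg=100, bias_strength=1.0, seed=3))
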