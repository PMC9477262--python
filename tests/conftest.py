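import numpy as np
import pytest

from stingcascade import ParameterVector, fig2_counts


@pytest.fixture(scope="session")
def fig2():
    """The bundled published frequency table for groups of 10 bees (N=92)."""
    return fig2_counts()


@pytest.fixture(scope="session")
def random_monotone():
    """Factory for random valid (monotone, in [0,1]) parameter vectors."""

    def make(rng: np.random.Generator, n: int) -> ParameterVector:
        return ParameterVector(tuple(np.sort(rng.uniform(0.0, 1.0, n))))

    return make
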