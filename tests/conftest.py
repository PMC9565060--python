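import numpy as np
import pandas as pd
import pytest

import riverfce as rf


@pytest.fixture(scope="session")
def system():
    """Packaged default indicator system: (hierarchy, ordered specs)."""
    return rf.default_system()


@pytest.fixture(scope="session")
def hierarchy(system):
    return system[0]


@pytest.fixture(scope="session")
def specs(system):
    return system[1]


@pytest.fixture(scope="session")
def spec_map(specs):
    return {s.id: s for s in specs}


@pytest.fixture(scope="session")
def published():
    """Published weight table split into indicator and criterion blocks."""
    return rf.published_indicator_weights(), rf.published_criterion_weights()


def random_reciprocal_matrix(rng: np.random.Generator, n: int) -> rf.JudgmentMatrix:
    """A random positive reciprocal matrix (entries lognormal around 1-9 scale)."""
    a = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = float(np.exp(rng.normal(0.0, 0.8)))
            a[i, j] = v
            a[j, i] = 1.0 / v
    return rf.JudgmentMatrix(a, tuple(f"e{k}" for k in range(n)))
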