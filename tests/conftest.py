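import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from trialtriplet import ContingencyTable2x2

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@st.composite
def tables_st(draw, max_n: int = 40, min_arm: int = 1):
    """Random 2x2 tables with both arms non-empty and N <= max_n."""
    n1 = draw(st.integers(min_arm, max_n - min_arm))
    n2 = draw(st.integers(min_arm, max_n - n1))
    a = draw(st.integers(0, n1))
    c = draw(st.integers(0, n2))
    return ContingencyTable2x2(a, n1 - a, c, n2 - c)


def random_tables(rng: np.random.Generator, n: int, max_arm: int = 200):
    """Vector of random tables for bulk property checks."""
    n1 = rng.integers(1, max_arm + 1, size=n)
    n2 = rng.integers(1, max_arm + 1, size=n)
    a = rng.integers(0, n1 + 1)
    c = rng.integers(0, n2 + 1)
    return [
        ContingencyTable2x2(int(ai), int(n1i - ai), int(ci), int(n2i - ci))
        for ai, n1i, ci, n2i in zip(a, n1, c, n2)
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251231)
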