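import numpy as np
import pytest

from twobytwo import Table2x2


@pytest.fixture
def worked_example() -> Table2x2:
    """The unbalanced 1/10 vs 5/10 table used throughout as the exemplar."""
    return Table2x2(y1=1, n1=10, y2=5, n2=10)


@pytest.fixture
def symmetric_table() -> Table2x2:
    return Table2x2(y1=3, n1=10, y2=3, n2=10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250923)


def random_interior_table(rng: np.random.Generator, max_n: int = 12) -> Table2x2:
    """A random table whose success total is away from both margins."""
    while True:
        n1 = int(rng.integers(2, max_n + 1))
        n2 = int(rng.integers(2, max_n + 1))
        y1 = int(rng.integers(0, n1 + 1))
        y2 = int(rng.integers(0, n2 + 1))
        t = Table2x2(y1, n1, y2, n2)
        if 0 < t.y_plus < t.n_plus:
            return t
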