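import numpy as np
import pandas as pd
import pytest

from exactanova import ExperimentTable, make_fixture


@pytest.fixture(scope="session")
def table1():
    """The printed unbalanced weight-gain experiment (15 observations)."""
    return make_fixture("table1")


def random_two_way(rng, a=None, b=None, min_n=1, max_n=4, balanced=False):
    """A random two-way table with all cells filled."""
    a = a or rng.integers(2, 4)
    b = b or rng.integers(2, 5)
    n_per = rng.integers(min_n, max_n + 1, size=(a, b))
    if balanced:
        n_per[:] = rng.integers(min_n, max_n + 1)
    rows = []
    for i in range(a):
        for j in range(b):
            for _ in range(n_per[i, j]):
                rows.append((f"a{i}", f"b{j}", rng.normal()))
    frame = pd.DataFrame(rows, columns=["A", "B", "y"])
    return ExperimentTable.from_dataframe(frame, response="y", factors=("A", "B"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
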