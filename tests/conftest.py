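import numpy as np
import pandas as pd
import pytest

from midtraject import expression_core as ec
from midtraject import synthetic_data as sd

TWO_CELLS = [("WT", 6, "SE"), ("WT", 12, "SE")]


@pytest.fixture(scope="session")
def small_design():
    return sd.make_design(6, n_batches=6, seed=1)


@pytest.fixture(scope="session")
def small_truth():
    return sd.make_truth(400, {1: 0.1, 2: 0.1, 3: 0.1}, 1.0, frac_compensated=0.5, seed=2)


@pytest.fixture(scope="session")
def small_counts(small_truth, small_design):
    return sd.simulate_counts(small_truth, small_design, seed=3)


@pytest.fixture(scope="session")
def two_cell_fit():
    """A fitted two-cell model shared by the contrast tests."""
    design = sd.make_design(6, cells=TWO_CELLS, n_batches=2, seed=0)
    # class-3 genes plant a WT temporal offset, giving this reduced design
    # a recoverable 12-vs-6 signal
    truth = sd.make_truth(300, {3: 0.4}, 1.0, seed=1, cells=TWO_CELLS)
    counts = sd.simulate_counts(truth, design, seed=2)
    counts = ec.low_count_filter(counts, 50)
    fit = ec.fit_nb_glm(counts, design)
    return truth, design, counts, fit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    return pd.DataFrame(
        [[2, 4], [10, 20]],
        index=["g1", "g2"],
        columns=["s1", "s2"],
    )
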