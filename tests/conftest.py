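import logging

import numpy as np
import pytest

import rehabselect as rs

# the subset-selection evaluator logs a warning for subsets KNN cannot use;
# exhaustive enumerations would otherwise flood the test log
logging.getLogger("rehabselect.selection").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cohort():
    """The default synthetic cohort: 120 cases, separation 3, balanced."""
    table, truth = rs.generate_table(rs.SynthConfig())
    return table


@pytest.fixture(scope="session")
def toy_table():
    """Well-separated two-blob table (10 + 10 cases) for exactness checks."""
    return rs.generate_separable_toy(n_per_class=10, dims=2, gap=10.0, seed=1)


@pytest.fixture(scope="session")
def tiny_table():
    """12-case synthetic table, small enough for exhaustive enumeration."""
    table, _ = rs.generate_table(rs.SynthConfig(n_cases=12, seed=100))
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
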