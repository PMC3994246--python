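import numpy as np
import pytest

from cvprotocols import SyntheticSpec, generate_classification, generate_regression


@pytest.fixture
def small_regression():
    """30×8 regression table, 3 informative columns, mild noise."""
    ds, truth = generate_regression(
        SyntheticSpec(n_samples=30, n_variables=8, n_informative=3,
                      coefficient_scale=1.0, noise_sd=0.5, seed=11)
    )
    return ds, truth


@pytest.fixture
def small_classification():
    """60×6 two-class table with a clear logistic signal."""
    ds, truth = generate_classification(
        SyntheticSpec(n_samples=60, n_variables=6, n_informative=2,
                      coefficient_scale=2.0, seed=5)
    )
    return ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
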