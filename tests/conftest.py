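import numpy as np
import pytest

from quiescence_mirnome import synthetic_data as synth
from quiescence_mirnome.core_io import ExpressionMatrix


@pytest.fixture
def small_config():
    """Desk-scale synthetic config used across stage tests."""
    return synth.SyntheticConfig(seed=11, n_mirnas=120, n_genes=600,
                                 target_set_sizes=[30] * 6)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_matrix(rng):
    vals = rng.normal(size=(12, 5))
    return ExpressionMatrix(
        vals,
        [f"f{i}" for i in range(12)],
        [f"s{j}" for j in range(5)],
    )
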