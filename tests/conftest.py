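import numpy as np
import pytest

from alpsfw.synthetic_data import make_gradient_table


@pytest.fixture(scope="session")
def gtab50():
    """Single-shell acquisition: 1 b0 + 50 directions at b=1000."""
    return make_gradient_table(50)


@pytest.fixture(scope="session")
def gtab_two_shell():
    """Two-shell acquisition (b=500/1000), well-posed for per-voxel FW fits."""
    return make_gradient_table(50, bvalues=(500.0, 1000.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
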