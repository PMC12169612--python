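import numpy as np
import pytest

import bchekit as bk
from bchekit import synthetic


@pytest.fixture(scope="session")
def toy_params() -> bk.KineticParams:
    return bk.TRUTH_SETS["toy"]


@pytest.fixture(scope="session")
def conditions() -> bk.AssayConditions:
    return bk.AssayConditions()


@pytest.fixture(scope="session")
def t_grid() -> np.ndarray:
    return np.arange(0.0, 601.0, 2.0)


@pytest.fixture(scope="session")
def coarse_grid() -> np.ndarray:
    return np.arange(0.0, 601.0, 20.0)


@pytest.fixture(scope="session")
def noiseless_toy_set(toy_params, conditions) -> bk.ProgressCurveSet:
    """Noiseless duplicate family at the reference inhibitor design."""
    return synthetic.generate_progress_set(
        toy_params, bk.MIXED_SCHEME, conditions, replicates=1
    )
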