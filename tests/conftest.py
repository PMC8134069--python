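import numpy as np
import pytest

from mechanostat import gating_spring as gs
from mechanostat import synthetic as syn

REFERENCE_T = 298.15


@pytest.fixture(scope="session")
def two_pop_params():
    """Reference two-population receiver used across the gating tests."""
    return syn.default_gating_params(T=REFERENCE_T)


@pytest.fixture(scope="session")
def displacement_grid():
    """61 displacements spanning +/-2 um (the standard acquisition grid)."""
    return np.linspace(-2e-6, 2e-6, 61)


@pytest.fixture(scope="session")
def noiseless_curve(two_pop_params, displacement_grid):
    K = gs.model_stiffness(displacement_grid, two_pop_params)
    return gs.StiffnessCurve(X=displacement_grid, K=K)


@pytest.fixture(scope="session")
def frap_truth():
    return syn.default_frap_fit()
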