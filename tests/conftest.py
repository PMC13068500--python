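import numpy as np
import pytest

from mossar import synthetic


@pytest.fixture(scope="session")
def plots56():
    return synthetic.generate_environment(n_plots=56, seed=7)


@pytest.fixture(scope="session")
def community56(plots56):
    truth = synthetic.hump_truth(seed=7)
    return synthetic.generate_community(plots56, truth)


@pytest.fixture(scope="session")
def transect_coords():
    """56 distinct sites along a short WGS84 transect."""
    return np.column_stack(
        [np.linspace(113.50, 113.58, 56), np.linspace(39.00, 39.07, 56)]
    )
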