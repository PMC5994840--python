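import numpy as np
import pytest

import funbayes as fb


@pytest.fixture
def wheat_grid():
    """250 equispaced wavelengths over 392-851 nm."""
    return fb.MeasurementGrid.equispaced(392.0, 851.0, 250)


@pytest.fixture
def unit_grid():
    return fb.MeasurementGrid.equispaced(0.0, 1.0, 101)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
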