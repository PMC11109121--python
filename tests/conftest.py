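import numpy as np
import pytest

from codrp import load_packaged_cohort
from codrp.drc import DoseSeries, make_dilution_series


@pytest.fixture(scope="session")
def cohort():
    """The packaged 14-patient EGFR-TKI cohort."""
    return load_packaged_cohort()


@pytest.fixture(scope="session")
def dose_grid():
    """Default 7-point, 3-fold dilution grid from 50 uM."""
    return make_dilution_series(50.0, 3.0, 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
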