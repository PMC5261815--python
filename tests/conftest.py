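import numpy as np
import pytest

import ferroflux as ff
from ferroflux.synth import generate_calibration_suite


@pytest.fixture(scope="session")
def ref_params():
    return ff.reference_parameters()


@pytest.fixture(scope="session")
def baseline(ref_params):
    """Unperturbed steady state of the reference model (normal diet)."""
    return ff.steady_state(ref_params)


@pytest.fixture(scope="session")
def suite(ref_params):
    """The full 344-record synthetic calibration design (fixed seed)."""
    return generate_calibration_suite(ref_params, seed=20240913 % 2**16)


@pytest.fixture(scope="session")
def suite_small(suite):
    """A cheap, still-informative subset used by fitting tests."""
    keep = {"lps_acute", "diet9w_high", "hampko_liver"}
    return [d for d in suite if d.name in keep]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
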