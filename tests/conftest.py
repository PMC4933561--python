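import numpy as np
import pytest

from nvcpipe.core import Timecourse
from nvcpipe.synthgen import BiphasicParams, biphasic_template, gen_timecourse


@pytest.fixture(scope="session")
def default_params() -> BiphasicParams:
    return BiphasicParams(onset_delay=0.8)


@pytest.fixture(scope="session")
def noiseless_trace(default_params) -> Timecourse:
    """Default biphasic template sampled at 20 Hz without noise."""
    return gen_timecourse(default_params, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def dense_template(default_params) -> Timecourse:
    """Continuum-limit oracle: the same template at 1 kHz."""
    t = np.arange(-5.0, 30.0, 0.001)
    return Timecourse(time=t, value=biphasic_template(default_params, t))
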