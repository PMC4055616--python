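import numpy as np
import pytest
from scipy.optimize import brentq

from phytogrowth.eos80 import sigma_t
from phytogrowth.hydrography import DepthProfile


def profile_from_sigma(depths, sigmas, station_id="test", salinity=35.0, **kwargs):
    """Build a DepthProfile whose EOS-80 sigma_t equals ``sigmas`` exactly.

    Temperature at each level is found by root-finding against the package's
    own density code, so tests can prescribe density structure directly.
    """
    depths = np.asarray(depths, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    temps = np.array(
        [brentq(lambda t, s=s: sigma_t(salinity, t) - s, -2.0, 40.0) for s in sigmas]
    )
    return DepthProfile(
        station_id=station_id,
        depth=depths,
        temperature=temps,
        salinity=np.full(depths.size, salinity),
        **kwargs,
    )


@pytest.fixture
def sigma_profile():
    return profile_from_sigma


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
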