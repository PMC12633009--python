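import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from syndecay import HotspotParams, OneCutParams, TwoCutParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Simulation validation protocol parameters (t = 0.25 subs/site,
#: 20 chromosomes x 1000 genes).
FIG2_T = 0.25
FIG2_GENOME = [1000] * 20


@pytest.fixture(scope="session")
def fig2_params():
    return {
        "one_cut": OneCutParams(kappa=0.1),
        "two_cut": TwoCutParams(gamma=0.1, theta=0.5),
        "hotspot": HotspotParams(kappa_h=0.5, kappa_c=0.01, r_hc=0.05, r_ch=0.01),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
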