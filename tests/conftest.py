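import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from burstevents.core import BurstParams


@pytest.fixture(scope="session")
def reference_params() -> BurstParams:
    """Reference parameter set: p1=0.95, tau_P=0.165 min, exponential
    inactive block of mean 100 min, tau_m=5 min (steady-state mean ~0.921)."""
    return BurstParams.from_inactive_mean(tau_P=0.165, tau_S=100.0, p1=0.95, tau_m=5.0)


@pytest.fixture(scope="session")
def scenario_sets():
    """The four reference inactive-phase compositions (tau_S1, tau_S2, tau_S3)
    with tau_P=1, tau_m=10, p1=0.9, p2=0.5."""
    return [(15.0, 2.0, 4.0), (10.0, 20.0, 6.0), (3.0, 10.0, 15.0), (5.0, 20.0, 8.0)]


def make_scenario_params(s):
    return BurstParams(
        tau_P=1.0, tau_S1=s[0], tau_S2=s[1], tau_S3=s[2], p1=0.9, p2=0.5, tau_m=10.0
    )
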