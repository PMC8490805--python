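import numpy as np
import pytest

import wardflow as wf

TANDEM_RULES = """\
# porter tandem: arrivals -> waiting -> in transit -> done
0 -> WAIT @ k0 [u_arrivals]
WAIT -> TRANSIT @ k1
TRANSIT -> 0 @ k2
"""


@pytest.fixture(scope="session")
def tandem_net() -> wf.FlowNetwork:
    return wf.parse_rule_file(TANDEM_RULES)


@pytest.fixture(scope="session")
def tandem_rates(tandem_net) -> wf.RateParameters:
    return wf.RateParameters(np.array([1.0, 0.2, 0.1]), tandem_net.rate_names)


@pytest.fixture()
def tandem_dynamics(tandem_net, tandem_rates) -> wf.LinearDynamics:
    return wf.build_system_matrices(tandem_net, tandem_rates)


@pytest.fixture(scope="session")
def square_wave_input():
    """Piecewise-constant arrival intensity alternating every 60 minutes."""

    def u(t):
        return np.array([4.0 if (int(t) // 60) % 2 == 0 else 8.0])

    return u


@pytest.fixture(scope="session")
def decay_net() -> wf.FlowNetwork:
    return wf.parse_rule_file("WAIT -> TRANSIT @ k1\n")
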