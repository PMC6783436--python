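import numpy as np
import pytest

import looplearn as ll


@pytest.fixture(scope="session")
def agent_design():
    """A fixed full-size agent-task design (4 conditions x 25 trials)."""
    return ll.build_design("agent_private", seed=42)


@pytest.fixture(scope="session")
def audience_design():
    return ll.build_design("audience_private", seed=42)


@pytest.fixture(scope="session")
def m6():
    return ll.get_model("agent_private", "M6_valence_SO")


@pytest.fixture(scope="session")
def m6_params():
    return ll.ParameterSet(
        alphas=np.array([0.12, 0.18, 0.10, 0.11]),
        init_values=np.array([50.0, 48.0, 52.0, 50.0]),
        noise_sd=8.0,
    )


@pytest.fixture(scope="session")
def quick_cfg():
    return ll.SamplerConfig.quick(seed=7)
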