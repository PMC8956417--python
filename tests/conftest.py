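import numpy as np
import pytest

from neuromark import ProtocolSpec, broadband_filter, generate_session
from neuromark.protocol import default_effects_group_a, default_effects_group_b


@pytest.fixture(scope="session")
def protocol() -> ProtocolSpec:
    return ProtocolSpec()


@pytest.fixture(scope="session")
def session_a(protocol):
    """One broadband-filtered group-A session (elevated frontal-central alpha,
    targeted Cz-Pz / Cz-Fp2 coherence, persistent D2 envelope)."""
    return broadband_filter(
        generate_session(default_effects_group_a(), protocol, seed=11, subject_id="sub-a"))


@pytest.fixture(scope="session")
def session_b(protocol):
    return broadband_filter(
        generate_session(default_effects_group_b(), protocol, seed=12, subject_id="sub-b"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
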