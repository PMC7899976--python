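import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mp_session_60s():
    """A 60 s predictable session, shared by the slower learner tests."""
    from msisim.motion import SessionSpec, generate_session

    return generate_session(SessionSpec(condition="M_P", total_duration=60.0, seed=1))
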