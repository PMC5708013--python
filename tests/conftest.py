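import pytest
from hypothesis import HealthCheck, settings

import scaldsim as ss

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def case_a_8s() -> ss.CaseResult:
    """Base scenario truncated to 8 s (covers the basal peak and most damage)."""
    return ss.run_case(ss.get_case("A"), t_end=8.0)


@pytest.fixture(scope="session")
def case_c_30s() -> ss.CaseResult:
    """Fabric off at 2.5 s, water cooling at 5 s, full 30 s horizon."""
    return ss.run_case(ss.get_case("C"))
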