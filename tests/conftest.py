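import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cdcea import paper_baseline_inputs, run_comparison  # noqa: E402


@pytest.fixture(scope="session")
def conv_inputs():
    return paper_baseline_inputs("conventional_care_failure")


@pytest.fixture(scope="session")
def tnf_inputs():
    return paper_baseline_inputs("tnf_failure")


@pytest.fixture(scope="session")
def conv_result(conv_inputs):
    """Base-case comparison, conventional-care failure population."""
    return run_comparison(conv_inputs)


@pytest.fixture(scope="session")
def tnf_result(tnf_inputs):
    """Base-case comparison, TNF-alpha-inhibitor failure population."""
    return run_comparison(tnf_inputs)
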