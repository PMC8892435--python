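import pytest

from aifannot import make_test_suite


@pytest.fixture(scope="session")
def clean_sim():
    """25 well-separated compounds, 3 fragments each, no noise."""
    return make_test_suite("clean", seed=7)


@pytest.fixture(scope="session")
def noisy_sim():
    """Clean compound set plus CV 0.2 intensity noise and 50 spurious peaks/scan."""
    return make_test_suite("noisy", seed=7)


@pytest.fixture(scope="session")
def coeluting_sim():
    """Five compound pairs sharing an RT apex and one fragment m/z."""
    return make_test_suite("co-eluting", seed=7)
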