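import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


from grnscape import zoo  # noqa: E402


@pytest.fixture(scope="session")
def toggle_entry():
    return zoo.make_toggle()


@pytest.fixture(scope="session")
def single_gene_entry():
    return zoo.make_single_gene()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
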