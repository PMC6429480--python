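import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from groovedock.fixtures import make_toy_complex, make_toy_template  # noqa: E402


@pytest.fixture(scope="session")
def toy9():
    """Planted 9-mer complex: receptor + relaxed peptide + anchor spec."""
    return make_toy_complex(9, seed=1)


@pytest.fixture(scope="session")
def template9():
    """Independent toy template (different planted peptide, same groove)."""
    return make_toy_template(9, seed=2)


@pytest.fixture(scope="session")
def toy9_sequence():
    from groovedock.fixtures import TOY_PEPTIDE_SEQUENCES

    return TOY_PEPTIDE_SEQUENCES[9]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
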