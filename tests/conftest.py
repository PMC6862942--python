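import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from usualintake.synthetic import GeneratorSpec, generate

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_two_day():
    """Vitamin-A-like two-recall data: realistic scale, ratio 2, known truth."""
    spec = GeneratorSpec(n_persons=1200, seed=42)
    table, truth = generate(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def vitaminE_two_day():
    """Vitamin-E-like two-recall data (small-unit scale, lambda well identified)."""
    spec = GeneratorSpec(n_persons=2000, beta0=3.0, seed=42)
    table, truth = generate(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def default_one_day(default_two_day):
    spec, table, truth = default_two_day
    return spec, table[table["day"] == 1].reset_index(drop=True), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
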