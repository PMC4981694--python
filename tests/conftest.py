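import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dietmodel.synthetic import (
    FixtureSpec,
    generate_food_table,
    pure_macro_config,
    pure_macro_table,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pure_table():
    return pure_macro_table()


@pytest.fixture(scope="session")
def pure_config():
    return pure_macro_config()


@pytest.fixture(scope="session")
def realistic_fixture():
    spec = FixtureSpec(seed=42)
    table, items = generate_food_table(spec)
    return spec, table, items


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
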