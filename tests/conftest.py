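import numpy as np
import pytest

from raresoil.core import CommunityTable, FunctionTable, DEFAULT_FUNCTION_SCHEMA
from raresoil.simulate import SimulationConfig, generate_dataset

GROUPS = ("archaea", "bacteria", "fungi", "protist")


def make_config(**kw) -> SimulationConfig:
    """Scaled-down simulation config for fast tests."""
    defaults = dict(
        n_samples=36,
        n_otus={g: 80 for g in GROUPS},
        group_depths={g: 500 for g in GROUPS},
        lognormal_shape={g: (0.0, 4.0) for g in GROUPS},
        seed=7,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(make_config())


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size default dataset (228 samples, paper depths)."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table(rng):
    counts = rng.integers(0, 40, size=(6, 10))
    counts[:, 3] += 1  # guarantee at least one non-empty column
    return CommunityTable(
        sample_ids=[f"s{i}" for i in range(6)],
        phylotype_ids=[f"p{j}" for j in range(10)],
        counts=counts,
        group="bacteria",
    )


@pytest.fixture
def function_table(rng):
    values = rng.uniform(0, 10, size=(12, 16))
    return FunctionTable(
        sample_ids=[f"s{i}" for i in range(12)],
        function_ids=list(DEFAULT_FUNCTION_SCHEMA),
        values=values,
        service_group={f: sg for f, (sg, _) in DEFAULT_FUNCTION_SCHEMA.items()},
        sign={f: s for f, (_, s) in DEFAULT_FUNCTION_SCHEMA.items()},
    )
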