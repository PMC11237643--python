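import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from soilfingerprint import AttributeTable, EnvTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_table() -> AttributeTable:
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(5, 8)),
        index=[f"S{i}" for i in range(5)],
        columns=[f"A{j}" for j in range(8)],
    )
    return AttributeTable(counts=counts, attribute_type="KO")


@pytest.fixture
def small_env() -> EnvTable:
    rng = np.random.default_rng(11)
    data = pd.DataFrame(
        {
            "bulk_density": rng.uniform(0.3, 1.5, 5),
            "cec": rng.uniform(8, 68, 5),
            "nitrogen": rng.uniform(0.3, 22, 5),
            "ph": rng.uniform(4.5, 8.2, 5),
            "soc": rng.uniform(3, 500, 5),
            "clay": rng.uniform(3, 57, 5),
            "biome": ["tundra", "tundra", "boreal_forest", "boreal_forest",
                      "tundra"],
        },
        index=pd.Index([f"S{i}" for i in range(5)], name="sample"),
    )
    return EnvTable(data=data)
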