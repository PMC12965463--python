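import numpy as np
import pandas as pd
import pytest

from redwind import SimulationConfig, generate_all


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=20240901, n_cities=6)


@pytest.fixture(scope="session")
def small_data(small_config):
    """One fixed small synthetic world shared across read-only tests."""
    return generate_all(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1729)


def make_generators(rows):
    """Generator table from (capacity, fuel, prime_mover, first_op, retirement)."""
    return pd.DataFrame(
        [
            {
                "plant_id": "P1",
                "generator_id": f"g{i}",
                "nameplate_capacity_mw": cap,
                "energy_source": fuel,
                "prime_mover": pm,
                "first_operation_year": fy,
                "retirement_year": ry,
            }
            for i, (cap, fuel, pm, fy, ry) in enumerate(rows)
        ]
    )
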