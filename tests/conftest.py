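import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from chromascape import simulate
from chromascape.colours import COLOURS

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def colour_table_small() -> pd.DataFrame:
    return simulate.gen_colour_table(12, seed=7)


@pytest.fixture(scope="session")
def tree_small():
    return simulate.gen_phylogeny(12, seed=7)


@pytest.fixture(scope="session")
def scenario_small() -> simulate.SyntheticScenario:
    return simulate.SyntheticScenario(seed=7, n_species=12, n_sites=15)


def profile(**pct) -> pd.Series:
    """Build one 10-colour profile Series; unnamed colours get 0."""
    values = {c: 0.0 for c in COLOURS}
    values.update(pct)
    return pd.Series(values, dtype=float)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
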