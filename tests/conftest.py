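import numpy as np
import pandas as pd
import pytest

from habindex.synth import SynthConfig, generate_study


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A small but fully featured synthetic study (5 habitats, 23 species)."""
    return SynthConfig(
        n_habitats=5,
        n_communities_per_habitat=3,
        n_specialists_per_habitat=3,
        n_generalists=8,
        generalist_breadth=3,
        first_year=1990,
        last_year=2012,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture
def toy_covers() -> pd.DataFrame:
    """Hand-written cover matrix: one 3-habitat generalist, one 2-habitat
    species with unequal covers, one specialist."""
    return pd.DataFrame(
        {
            "species": ["gen3", "gen3", "gen3", "two", "two", "solo"],
            "habitat": ["A", "B", "C", "A", "B", "C"],
            "cover": [0.05, 0.02, 0.01, 0.06, 0.02, 0.04],
        }
    )


@pytest.fixture
def toy_areas() -> pd.DataFrame:
    return pd.DataFrame({"habitat": ["A", "B", "C"], "area": [90.0, 10.0, 100.0]})
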