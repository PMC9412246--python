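import numpy as np
import pandas as pd
import pytest

import reefprod as rp
from reefprod.productivity import group_rows


@pytest.fixture
def toy_traits() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_id": ["spA", "spB", "spC"],
            "family": ["Apogonidae", "Labridae", "Lutjanidae"],
            "lw_a": [0.01, 0.02, 0.015],
            "lw_b": [3.0, 2.9, 3.1],
            "l_max_cm": [10.0, 20.0, 45.0],
            "k_max_per_yr": [2.5, 0.6, 0.35],
        }
    )


@pytest.fixture
def toy_diel() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_id": ["spA", "spB", "spC"],
            "diel_raw": ["nocturnal", "diurnal", "both"],
            "evidence": ["literature", "reference-work", "expert"],
        }
    )


@pytest.fixture
def toy_surveys() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "survey_id": ["sv1", "sv2"],
            "site_id": ["siteA", "siteB"],
            "exposure": ["sheltered", "exposed"],
            "area_m2": [100.0, 250.0],
        }
    )


@pytest.fixture
def toy_obs() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "survey_id": ["sv1", "sv1", "sv2"],
            "species_id": ["spA", "spB", "spC"],
            "length_cm": [5.0, 12.0, 30.0],
            "count": [10, 2, 1],
        }
    )


@pytest.fixture
def toy_enriched(toy_obs, toy_traits, toy_diel):
    enriched, dropped = rp.join_observations(
        toy_obs, toy_traits, rp.pool_diel(toy_diel)
    )
    assert len(dropped) == 0
    return enriched


@pytest.fixture(scope="session")
def small_synth():
    """A small but full synthetic dataset shared by slower tests."""
    config = rp.SynthConfig(
        n_sites_sheltered=3, n_sites_exposed=3, surveys_per_site=3, area_m2=100.0
    )
    traits, diel, surveys, obs, truth = rp.generate_dataset(config, 42)
    return config, traits, diel, surveys, obs, truth


@pytest.fixture(scope="session")
def small_summaries(small_synth):
    _, traits, diel, surveys, obs, _ = small_synth
    enriched, _ = rp.join_observations(obs, traits, rp.pool_diel(diel))
    return rp.survey_summaries(enriched, surveys, n_iter=200, seed=11)


@pytest.fixture(scope="session")
def small_group_rows(small_summaries):
    return group_rows(small_summaries)


@pytest.fixture(scope="session")
def quick_fit(small_group_rows):
    config = rp.ModelConfig(
        response="biomass", n_chains=2, n_iter_per_chain=1500, seed=5
    )
    return rp.fit_hierarchical_model(small_group_rows, config)
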