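import numpy as np
import pandas as pd
import pytest

from yieldcast import (
    FeatureInfo,
    LearnerSpec,
    PanelDataset,
    SyntheticConfig,
    generate_panel,
)


def make_tiny_panel(columns: dict, meta: dict, response=None, years=None,
                    location="L0", state="S0", district="D0", area=100.0):
    """Hand-build a panel from plain column dicts (single location)."""
    n = len(next(iter(columns.values()))) if columns else len(response)
    frame = pd.DataFrame(
        {
            "location_id": location,
            "year": years if years is not None else np.arange(2000, 2000 + n),
            "state": state,
            "district": district,
            "response": response if response is not None else np.zeros(n),
            "harvested_area": area,
            **columns,
        }
    )
    return PanelDataset(frame, meta)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale panel: 10 counties, 19 years, 1 weather variable."""
    return SyntheticConfig(
        n_locations=10,
        n_weather_vars=1,
        weather_weeks=(14, 20),
        n_soil_features=2,
        planting_weeks=(14, 16),
        noise_sd=50.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_panel(small_config)


@pytest.fixture(scope="session")
def noiseless_panel():
    """Response exactly affine in year per location (no feature effects)."""
    return generate_panel(
        SyntheticConfig(
            n_locations=6,
            n_weather_vars=1,
            weather_weeks=(14, 18),
            n_soil_features=2,
            planting_weeks=(14, 15),
            noise_sd=0.0,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def base_specs():
    return [
        LearnerSpec("lin", "linear"),
        LearnerSpec("dummy", "dummy_mean"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
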