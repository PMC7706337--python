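import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phytosense.design import CONTROL, STRESSED, Watering, WateringState, build_design
from phytosense.imaging import extract_indices, indices_to_frame
from phytosense.render import render_plant_images
from phytosense.sensor import compute_response, daily_mean, normalize_nr, subdaily_nr
from phytosense.stats import build_feature_table
from phytosense.synthetic import (
    GeneratorConfig,
    sample_physiology,
    simulate_latent_states,
    synthesize_all_traces,
)

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def main_design():
    return build_design("MAIN")


@pytest.fixture(scope="session")
def pilot_design():
    return build_design("PILOT")


@pytest.fixture(scope="session")
def small_design():
    """A short drought design used where full-length runs are unnecessary."""
    stressed = (
        [WateringState(Watering.FULL)]
        + [WateringState(Watering.WITHHELD)] * 5
        + [WateringState(Watering.REWATERED)] * 2
    )
    control = [WateringState(Watering.FULL)] * 8
    return build_design(
        None,
        duration_days=8,
        photoperiod_h=12.0,
        sampling_interval_min=15,
        schedule={CONTROL: control, STRESSED: stressed},
        imaging_days=(0, 2, 4, 6),
        physio_days=(0, 4, 7),
        name="small",
    )


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def main_run(gen_config, main_design):
    """One full default synthetic run shared across the suite.

    Returns a dict of every intermediate the downstream stages consume.
    """
    states = simulate_latent_states(gen_config, main_design)
    traces = synthesize_all_traces(states, gen_config, main_design)
    physio = sample_physiology(states, gen_config, main_design)
    response = compute_response(traces)
    daily = daily_mean(response, main_design)
    nr = normalize_nr(daily)
    nr_fine = subdaily_nr(response)
    records = [
        extract_indices(render_plant_images(s, gen_config, day))
        for s in states
        for day in main_design.imaging_days
    ]
    indices = indices_to_frame(records)
    features = build_feature_table(indices, daily, physio)
    return {
        "states": states,
        "traces": traces,
        "physio": physio,
        "response": response,
        "daily": daily,
        "nr": nr,
        "nr_fine": nr_fine,
        "indices": indices,
        "features": features,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
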