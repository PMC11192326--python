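import numpy as np
import pandas as pd
import pytest

from earlyerp.layout import build_adjacency, make_layout
from earlyerp.simulate import SimParams, default_templates


@pytest.fixture(scope="session")
def layout():
    return make_layout()


@pytest.fixture(scope="session")
def adjacency(layout):
    return build_adjacency(layout)


@pytest.fixture()
def quiet_params():
    """All stochastic background silenced: planted components only."""
    return SimParams(
        component_templates=default_templates(1),
        noise_sd=0.0,
        pink_sd=0.0,
        alpha_amplitude=0.0,
        prestim_alpha_uv=0.0,
        drift_amplitude=0.0,
        blink_rate=0.0,
        amplitude_scale_sd=0.0,
        participant_effect_sd=0.0,
        trigger_lag_ms=0.0,
        seed=0,
    )


def simple_plan(n_trials=4, categories=("spider", "wheel"), location="FIX", soa_ms=1000.0):
    """Minimal fixation trial plan with onsets on exact sample boundaries."""
    cats = [categories[i % len(categories)] for i in range(n_trials)]
    return pd.DataFrame(
        {
            "trial_index": np.arange(n_trials),
            "category": cats,
            "location": [location] * n_trials,
            "onset_time_ms": 2000.0 + soa_ms * np.arange(n_trials),
            "iti_ms": soa_ms - 150.0,
            "block": 0,
            "dot_change": False,
            "stimulus_ms": 150.0,
        }
    )


@pytest.fixture()
def plan_factory():
    return simple_plan
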