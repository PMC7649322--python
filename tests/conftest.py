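"""Shared fixtures.

The full pipeline runs (two-bar and occluded-plaid simulations) are
session-scoped: they take seconds to tens of seconds each and several test
modules interrogate the same traces.
"""

import numpy as np
import pytest

from mtsurround.config import ModelParams
from mtsurround.stimuli import (StimulusSpec, crossing_bars, occluded_plaid,
                                plaid_spec, single_bar)
from mtsurround.mt_dynamics import run_model


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def bars_stimulus(params):
    spec = StimulusSpec(kind="crossing_bars")
    return (spec,) + crossing_bars(spec, params)


@pytest.fixture(scope="session")
def bars_trace(params, bars_stimulus):
    _, seq, gt = bars_stimulus
    return run_model(seq, params, mode="component"), gt


@pytest.fixture(scope="session")
def single_bar_stimulus(params):
    spec = StimulusSpec(kind="single_bar", orientations=(45.0,),
                        directions=(0.0,), n_frames=120)
    return (spec,) + single_bar(spec, params)


@pytest.fixture(scope="session")
def plaid_stimulus(params):
    spec = plaid_spec()
    return (spec,) + occluded_plaid(spec, params)


@pytest.fixture(scope="session")
def plaid_traces(params, plaid_stimulus):
    _, seq, gt = plaid_stimulus
    return {mode: run_model(seq, params, mode=mode)
            for mode in ("component", "pattern")}, gt


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
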