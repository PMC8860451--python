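"""Shared synthetic-session fixtures.

Sessions are generated at 100 Hz with a shortened ITI so the whole suite
stays fast; every analysis operates on sampling-rate-agnostic quantities.
"""

import numpy as np
import pytest

import ramptime as rt
from ramptime import preprocess as pp

FS = 100.0


def fast_task(**kw):
    kw.setdefault("iti_end", 9.0)
    kw.setdefault("sampling_rate", FS)
    return rt.TaskConfig(**kw)


@pytest.fixture(scope="session")
def ramp_session():
    return rt.make_session(rt.GenerativeParams(n_trials=150), fast_task(), seed=7)


@pytest.fixture(scope="session")
def step_session():
    return rt.make_session(
        rt.GenerativeParams(n_trials=150, dynamics_mode="step"), fast_task(), seed=8
    )


@pytest.fixture(scope="session")
def ramp_dff(ramp_session):
    return pp.compute_dff(
        ramp_session.channels["gcamp"], FS, "moving_average", ramp_session.trials
    )


@pytest.fixture(scope="session")
def ramp_control_dff(ramp_session):
    return pp.compute_dff(
        ramp_session.channels["control"], FS, "moving_average", ramp_session.trials
    )


@pytest.fixture(scope="session")
def step_dff(step_session):
    return pp.compute_dff(
        step_session.channels["gcamp"], FS, "moving_average", step_session.trials
    )
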