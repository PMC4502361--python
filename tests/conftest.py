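"""Shared fixtures: small calibrated models and synthetic cohort tables.

The ``micro`` preset (24 channels, 0.25-s stimuli, 32 kHz) backs most unit
tests; the ``desk`` preset (64 channels, 1-s stimuli) backs the
acceptance-level checks.  Both are session-scoped because calibration and
response-surface construction dominate the suite's runtime.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from angain.calibration import fit_healthy_gain
from angain.fixtures import FixtureSpec, make_control_table, make_patient_table
from angain.model import AuditoryModel, ResponseSurface, preset


@pytest.fixture(scope="session")
def micro_model() -> AuditoryModel:
    model = AuditoryModel(preset("micro"))
    model.calibrate(seed=1)
    return model


@pytest.fixture(scope="session")
def desk_model() -> AuditoryModel:
    model = AuditoryModel(preset("desk"))
    model.calibrate(seed=1)
    return model


@pytest.fixture(scope="session")
def desk_surface(desk_model) -> ResponseSurface:
    return ResponseSurface(desk_model).build()


@pytest.fixture(scope="session")
def micro_surface(micro_model) -> ResponseSurface:
    return ResponseSurface(micro_model).build()


@pytest.fixture(scope="session")
def control_table():
    return make_control_table(FixtureSpec())


@pytest.fixture(scope="session")
def patient_table():
    return make_patient_table(FixtureSpec())


@pytest.fixture(scope="session")
def healthy_fit(desk_surface, control_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_healthy_gain(control_table, desk_surface)
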