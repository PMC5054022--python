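"""Shared fixtures: the reference cell and the (expensive) analysis pipelines
are computed once per session and reused by unit, property and acceptance
tests."""

import numpy as np
import pytest

from crcell import reference_cr_cell
from crcell.repro import (
    a_activation_pipeline,
    a_inactivation_pipeline,
    a_recovery_pipeline,
    ca_persistent_pipeline,
    excitability_battery,
    h_tail_pipeline,
    na_activation_pipeline,
    passive_pipeline,
)


@pytest.fixture(scope="session")
def ref_model():
    return reference_cr_cell()


@pytest.fixture(scope="session")
def a_iso(ref_model):
    return ref_model.isolated("I_A")


@pytest.fixture(scope="session")
def na_iso(ref_model):
    return ref_model.isolated("I_Na")


@pytest.fixture(scope="session")
def a_activation(ref_model):
    return a_activation_pipeline(ref_model, dt=0.01)


@pytest.fixture(scope="session")
def a_inactivation(ref_model):
    return a_inactivation_pipeline(ref_model, dt=0.01)


@pytest.fixture(scope="session")
def a_recovery(ref_model):
    return a_recovery_pipeline(ref_model, dt=0.01)


@pytest.fixture(scope="session")
def na_activation(ref_model):
    return na_activation_pipeline(ref_model, dt=0.005)


@pytest.fixture(scope="session")
def h_tail(ref_model):
    return h_tail_pipeline(ref_model, dt=0.05)


@pytest.fixture(scope="session")
def passive(ref_model):
    return passive_pipeline(ref_model, dt=0.01)


@pytest.fixture(scope="session")
def ca_persistent(ref_model):
    return ca_persistent_pipeline(ref_model, dt=0.01)


@pytest.fixture(scope="session")
def battery(ref_model):
    return excitability_battery(ref_model, dt=0.01, pulse_amp=11.0)
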