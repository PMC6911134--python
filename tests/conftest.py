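"""Shared fixtures: noise-free simulated records used across the suite."""

import numpy as np
import pytest

from weanlab.simulate import (PatientParams, SimConfig, atc_settings,
                              ps_settings, simulate_record)
from weanlab.waveforms import WaveformRecord


@pytest.fixture(scope="session")
def patient():
    return PatientParams()


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free recording configuration for exactness checks."""
    return SimConfig(duration=90.0, seed=7, pes_noise_sd=0.0,
                     cardiac_artifact_amplitude=0.0)


@pytest.fixture(scope="session")
def ps_record(patient, clean_config):
    return simulate_record(patient, ps_settings(peep=4.0, ps=7.0),
                           clean_config)


@pytest.fixture(scope="session")
def atc_record(patient, clean_config):
    return simulate_record(patient, atc_settings(peep=4.0, fraction=1.0),
                           clean_config)


@pytest.fixture()
def sine_record():
    """Analytic record: 0.25 Hz sine flow, constant pressures, 60 s."""
    fs = 200.0
    t = np.arange(int(60 * fs)) / fs
    flow = 0.5 * np.sin(2 * np.pi * 0.25 * t)
    return WaveformRecord(time=t, flow=flow, paw=np.full(t.size, 5.0),
                          pes=np.full(t.size, 8.0), sampling_rate=fs)
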