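"""Shared fixtures: geometry, small simulations, lead fields."""

import numpy as np
import pytest

from opmpipe import synthetic
from opmpipe.forward import HeadModel, LeadField, make_grid


@pytest.fixture(scope="session")
def array():
    """Default 45-sensor dual-axis array (90 channels)."""
    return synthetic.make_sensor_array(45, seed=1)


@pytest.fixture(scope="session")
def head_model():
    return HeadModel()


@pytest.fixture(scope="session")
def coarse_grid(head_model):
    """10 mm grid: fast enough for whole-map scans in unit tests."""
    return make_grid(head_model, resolution=0.010)


@pytest.fixture(scope="session")
def coarse_lead_fields(head_model, array, coarse_grid):
    return LeadField.compute(head_model, array, coarse_grid)


@pytest.fixture(scope="session")
def fine_lead_fields(head_model, array):
    """5 mm grid lead fields - the pipeline's operative resolution."""
    grid = make_grid(head_model, resolution=0.005)
    return LeadField.compute(head_model, array, grid)


@pytest.fixture(scope="session")
def marker_layout():
    return synthetic.default_marker_layout()


@pytest.fixture(scope="session")
def still_epochs(array, head_model):
    """Epochs from a motionless, artefact-free bilateral-source recording at
    high SNR - the controlled localisation scenario."""
    from opmpipe import preprocess

    traj = synthetic.simulate_motion(40.0, translation_range=(0, 0, 0),
                                     rotation_range=(0, 0, 0), seed=0)
    stim = synthetic.StimulusTrain.regular(40.0)
    noise = synthetic.NoiseModel(white_density=15e-15)
    room = synthetic.RoomFieldModel(B0=np.zeros(3), G=np.zeros((3, 3)))
    srcs = synthetic.bilateral_auditory_sources()
    rec, gt = synthetic.simulate_recording(array, traj, room, srcs, stim, noise,
                                           head_model=head_model, rate=1000.0,
                                           seed=5, peak_moment=50e-9)
    rec = preprocess.filter_zero_phase(rec, "highpass", 2.0, 5)
    rec = preprocess.filter_zero_phase(rec, "lowpass", 40.0, 6)
    return preprocess.epoch_and_baseline(rec)
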