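"""Shared fixtures: a small spherical array, transmit sequence, and pulse.

The reduced 64-element array keeps simulation-based tests fast; it shares
the published aperture (57 mm on a 40 mm sphere) and frequency (4 MHz,
75% bandwidth), so the diffraction scale matches the full system.
"""

import numpy as np
import pytest
from hypothesis import settings

import paulm
from paulm.geometry import Sequence

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


FS = 20.83e6
FRAME_RATE = 215.0


@pytest.fixture(scope="session")
def geom64():
    return paulm.build_spherical_array(64, 40.0, 57.0, layout_seed=0)


@pytest.fixture(scope="session")
def geom256():
    return paulm.build_spherical_array(256, 40.0, 57.0, layout_seed=0)


@pytest.fixture(scope="session")
def seq4(geom64):
    tx = paulm.select_tx_subset(geom64, 4)
    return Sequence(tx_indices=tx, pulse_repetition_interval=1.0 / (FRAME_RATE * 4),
                    fs=FS, mode="us")


@pytest.fixture(scope="session")
def pulse():
    return paulm.gaussian_pulse(4e6, 0.75, FS)


@pytest.fixture(scope="session")
def grid21():
    return paulm.VoxelGrid.centered((21, 21, 21), 0.06)
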