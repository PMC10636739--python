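"""Shared fixtures: textured scenes and small rendered sequences.

Everything is generated programmatically and seeded, so the suite needs
no stored image data.
"""

import numpy as np
import pytest

from endomosaic.config import RunConfig
from endomosaic.synthetic_data import generate_scene, make_sequence


@pytest.fixture(scope="session")
def textured_scene():
    """512x512 keypoint-rich value-noise scene."""
    return generate_scene("textured", 512, seed=7)


@pytest.fixture(scope="session")
def small_scene():
    """256x256 textured scene for cheap warping tests."""
    return generate_scene("textured", 256, seed=3)


@pytest.fixture(scope="session")
def pan_sequence():
    """Clean 8-frame pure-translation pan with known ground truth."""
    return make_sequence(
        n_frames=8,
        trajectory_model="pan",
        magnitude=(4.0, 0.0),
        frame_size=(100, 100),
        seed=5,
    )


@pytest.fixture()
def cfg():
    return RunConfig(seed=0)


def corner_error(t_est, t_true, size=100):
    """Mean displacement of the four image corners between two affines."""
    c = np.array(
        [[0.0, 0.0], [size - 1.0, 0.0], [0.0, size - 1.0], [size - 1.0, size - 1.0]]
    )
    return float(np.linalg.norm(t_est.apply(c) - t_true.apply(c), axis=1).mean())
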