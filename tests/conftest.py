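import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from qlus import RoiSpec, UltrasoundFrame


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_frame(pixels, zone="RAU", subject="S001", machine="venue50"):
    return UltrasoundFrame(
        pixels=np.asarray(pixels, dtype=np.uint8),
        subject_id=subject,
        zone=zone,
        machine_id=machine,
    )


def full_mask_spec(height, width):
    """An RoiSpec whose band covers rows [0, height) across all columns."""
    return RoiSpec(
        pleural_polyline=((0, 0.0), (width - 1, 0.0)),
        lateral_bounds=(0, width),
        depth_px=height,
    )


@pytest.fixture
def frame_factory():
    return make_frame
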