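import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # makes oracles importable

from mimizutrack.imaging_io import Calibration, TrajectoryRecord
from mimizutrack.skeletonization import Skeleton


@pytest.fixture
def cal() -> Calibration:
    """Study calibration: 0.2 mm/px, 1 s frames."""
    return Calibration(mm_per_pixel=0.2, frame_interval=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_skeleton(pixels, shape=(64, 64)) -> Skeleton:
    return Skeleton(pixels=np.array(sorted(set(map(tuple, pixels)))), shape=shape)


def make_record(i, head, tail, center=None, length=10.0, status="ok", t=None):
    return TrajectoryRecord(
        frame_index=i, time_s=float(i if t is None else t),
        head_xy=head, center_xy=center, tail_xy=tail,
        length_mm=length, status=status,
    )
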