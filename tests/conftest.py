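import pytest

from smoketop.puff_segmentation import SegmentationParams
from smoketop.session_model import ProtocolSchedule, ProtocolSegment
from smoketop.synthetic_session import SimulationConfig


@pytest.fixture
def seg_params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture
def short_schedule() -> ProtocolSchedule:
    """A compressed protocol for fast unit tests (5.5 min)."""
    return ProtocolSchedule(
        segments=(
            ProtocolSegment(activity="rest", duration_s=40),
            ProtocolSegment(activity="packing", duration_s=20),
            ProtocolSegment(activity="smoking_left", duration_s=120),
            ProtocolSegment(activity="smoking_right", duration_s=120),
            ProtocolSegment(activity="other_movement", duration_s=30),
        )
    )


@pytest.fixture
def short_config(short_schedule) -> SimulationConfig:
    return SimulationConfig(
        seed=11, schedule=short_schedule, n_puffs_per_hand=4, noise_sd=0.0
    )
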