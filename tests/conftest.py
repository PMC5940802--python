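import pytest

from bitescope.core_data import VideoRecord
from bitescope.simulate import VideoSimConfig, simulate_videos


def make_record(**overrides) -> VideoRecord:
    base = dict(
        video_id="v0",
        context="benign",
        n_bites=1,
        puncture_visible=False,
        head_shake=False,
        hold_gt_1s=False,
        interaction_duration_s=30.0,
        dog_size="big",
        dog_breed="crossbreed",
        victim_age="adult",
        victim_sex="male",
        bite_site="limbs",
        initiator="dog",
        location="indoor",
        handler_sex="missing",
    )
    base.update(overrides)
    return VideoRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def study_scale_records():
    """A 143-video synthetic dataset at the study's marginal frequencies."""
    return simulate_videos(VideoSimConfig(n_videos=143, seed=20_260_920))
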