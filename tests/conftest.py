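import numpy as np
import pytest

from enskit.kymograph import build_kymograph
from enskit.segmentation import BowelSegmenter
from enskit.synthetic import MotilitySpec, WaveSpec, generate_motility_video

# One antegrade wave that traverses the full imaged length of the small
# test frame: 80 px/s sweeps ~±350 px around the mid-frame origin within
# its active window, far beyond the 200-px frame.
FULL_LENGTH_WAVE = WaveSpec(
    onset_s=12.0,
    origin_fraction=0.5,
    velocity_px_per_s=80.0,
    amplitude_fraction=0.3,
    spatial_halfwidth_px=15.0,
    temporal_halfwidth_s=3.0,
)


def small_spec(**overrides) -> MotilitySpec:
    """A desk-scale recording: 24 s at 15 fps, 80 x 200 px, 40 px bowel."""
    params = dict(
        duration_s=24.0,
        frame_rate_fps=15.0,
        frame_height_px=80,
        frame_width_px=200,
        baseline_width_px=40.0,
        wave_list=(FULL_LENGTH_WAVE,),
        noise_sd=5.0,
        seed=7,
    )
    params.update(overrides)
    return MotilitySpec(**params)


@pytest.fixture(scope="session")
def single_wave_video():
    spec = small_spec()
    frames, truth = generate_motility_video(spec)
    return spec, frames, truth


@pytest.fixture(scope="session")
def single_wave_kymo(single_wave_video):
    spec, frames, truth = single_wave_video
    dm = build_kymograph(frames, BowelSegmenter(), frame_rate_fps=spec.frame_rate_fps)
    return spec, dm, truth


@pytest.fixture(scope="session")
def ttx_video():
    spec = small_spec(neurogenic_enabled=False)
    frames, truth = generate_motility_video(spec)
    return spec, frames, truth


@pytest.fixture(scope="session")
def ttx_kymo(ttx_video):
    spec, frames, truth = ttx_video
    dm = build_kymograph(frames, BowelSegmenter(), frame_rate_fps=spec.frame_rate_fps)
    return spec, dm, truth
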