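import numpy as np
import pytest

from veinlive.synth import (NoiseModel, PulseModel, SceneConfig,
                            finger_transmission, generate_vein_pattern,
                            render_clip)

SMALL = SceneConfig(width=160, height=120, seed=7)


@pytest.fixture(scope="session")
def small_scene():
    return SMALL


@pytest.fixture(scope="session")
def small_pattern():
    A, mask = generate_vein_pattern(SMALL)
    return A, mask, finger_transmission(SMALL)


@pytest.fixture(scope="session")
def clean_live_clip(small_pattern):
    """Noise-free live clip with a known heart rate (160 x 120, 180 frames)."""
    A, mask, B = small_pattern
    clip, gt = render_clip(A, mask, PulseModel(f_heart=1.4),
                           NoiseModel(gaussian_sigma=0.0), live=True,
                           base_transmission=B, seed=11, quantize=False)
    return clip, gt


@pytest.fixture(scope="session")
def noisy_live_clip(small_pattern):
    A, mask, B = small_pattern
    clip, gt = render_clip(A, mask, PulseModel(f_heart=1.3), NoiseModel(),
                           live=True, base_transmission=B, seed=13)
    return clip, gt
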