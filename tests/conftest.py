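import numpy as np
import pytest

from phonokit import PhonationParameters, simulate_recording


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free-ish periodic multimodal recording, 1 s at study rates."""
    params = PhonationParameters(
        f0_hz=100.0, duration_s=1.0, video_duration_s=0.6,
        gap_area_mm2=1.0, amp_left_mm2=4.0, amp_right_mm2=5.0,
        phase_offset_cycles=0.1, jitter_cv=0.0, shimmer_cv=0.0,
        noise_db_audio=-60.0, noise_db_psub=-60.0,
        noise_floor_audio_pa=0.0, noise_floor_psub_pa=0.0,
        seed=3,
    )
    return simulate_recording(params)


@pytest.fixture(scope="session")
def perturbed_params():
    """500-cycle record with known period/amplitude perturbation."""
    return PhonationParameters(
        f0_hz=100.0, duration_s=5.0, video_duration_s=None,
        jitter_cv=0.01, shimmer_cv=0.02,
        noise_db_audio=float("-inf"), noise_floor_audio_pa=0.0,
        noise_db_psub=float("-inf"), noise_floor_psub_pa=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def rendered_stack():
    """200-frame synthetic high-speed stack with ground-truth masks."""
    from phonokit import render_frames

    params = PhonationParameters(
        f0_hz=100.0, duration_s=1.0, video_duration_s=0.05,
        gap_area_mm2=1.0, amp_left_mm2=4.0, amp_right_mm2=5.0,
        phase_offset_cycles=0.1, seed=3,
    )
    stack, masks = render_frames(params, resolution=256, pixel_scale_mm=0.1, n_frames=200)
    return params, stack, masks
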