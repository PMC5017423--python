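import numpy as np
import pytest

from pillarbeat import DirectionField, OpticsModel, TwitchWaveform, default_fixture
from pillarbeat.simulate import make_lattice, render_stack


@pytest.fixture(scope="session")
def small_noisefree():
    """3x3 lattice, 5 s at 25 fps, 1 Hz / 3 um beating along 90 deg, no noise."""
    return default_fixture(seed=7, rows=3, cols=3, duration_s=5.0)


@pytest.fixture(scope="session")
def small_snr10():
    """Same scene at SNR ~ 10 (signal 1800, noise sd 180)."""
    return default_fixture(seed=7, rows=3, cols=3, duration_s=5.0, noise_sd=180.0)


@pytest.fixture(scope="session")
def static_stack():
    """Zero-amplitude stack: every frame identical up to (zero) noise."""
    waveform = TwitchWaveform(amplitude_um=0.0)
    centers = make_lattice(2, 2, 23.0)
    return render_stack(centers, waveform, DirectionField(), OpticsModel(),
                        n_frames=60, seed=3)


@pytest.fixture(scope="session")
def tracked_small(small_noisefree):
    """Pipeline intermediates on the small noise-free fixture."""
    from pillarbeat.detect import detect_pillars, select_reference_frame
    from pillarbeat.track import estimate_reference, to_displacement, track_pillars

    stack, truth = small_noisefree
    ref_idx = select_reference_frame(stack.data)
    pillars = detect_pillars(stack.data[ref_idx], 16.0, 36.8)
    trajectories = track_pillars(stack, pillars, 10.0, reference_frame=ref_idx)
    series = [
        to_displacement(t, estimate_reference(t), stack.pixel_size_um,
                        stack.frame_rate_fps)
        for t in trajectories
    ]
    return stack, truth, pillars, trajectories, series
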