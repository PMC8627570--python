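"""Shared fixtures: synthetic swimmers at the three treatment-group parameter
sets, and one rendered-and-tracked trial reused by the image-pipeline tests
(rendering plus skeletonization is the slow part, so it is session-scoped).
"""

import numpy as np
import pytest

from swimtrack.synthetic import (
    RenderSpec,
    SwimmerParams,
    generate_midline_sequence,
    render_frames,
)
from swimtrack.tracking import track_stack

FPS = 250.0

SHAM = dict(wavelength_bl=0.79, frequency_hz=3.6, amp_pp_tail_bl=0.16,
            amp_ratio=4.8, speed_bl_s=1.83)
FIFTH_GILL = dict(wavelength_bl=0.53, frequency_hz=4.1, amp_pp_tail_bl=0.11,
                  amp_ratio=1.7, speed_bl_s=1.12)
MID_BODY = dict(wavelength_bl=0.61, frequency_hz=3.7, amp_pp_tail_bl=0.13,
                amp_ratio=1.9, speed_bl_s=1.12)


@pytest.fixture(scope="session")
def sham_midlines():
    """Noise-free sham-parameter midline sequence, 1.6 s at 250 fps."""
    return generate_midline_sequence(SwimmerParams(**SHAM), FPS, 400)


@pytest.fixture(scope="session")
def fifth_gill_midlines():
    return generate_midline_sequence(SwimmerParams(**FIFTH_GILL), FPS, 400)


@pytest.fixture(scope="session")
def rendered_sham(sham_midlines):
    """Rendered silhouette stack of the sham swimmer with px ground truth."""
    return render_frames(sham_midlines.observed, RenderSpec(pixels_per_bl=100))


@pytest.fixture(scope="session")
def tracked_sham(rendered_sham):
    """Midlines re-extracted from the rendered sham stack."""
    return track_stack(rendered_sham.frames, FPS)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
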