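import numpy as np
import pytest

from fpia_quant.core_io import CLINICAL_FRAME_SPEC, parse_frame_schedule
from fpia_quant.phantom import PhantomSpec, generate_study, simulate_aif

SMALL_GRID = (32, 32, 24)


@pytest.fixture(scope="session")
def clinical_schedule():
    """The 28-frame, 66.5-min clinical acquisition schedule."""
    return parse_frame_schedule(CLINICAL_FRAME_SPEC)


@pytest.fixture(scope="session")
def aif(clinical_schedule):
    """Default tri-exponential bolus input function on a 1-s grid."""
    t = np.arange(0.0, clinical_schedule.total_duration_s + 0.5) / 60.0
    return simulate_aif(times_min=t)


@pytest.fixture(scope="session")
def clean_study():
    """Small noiseless, unblurred grade-IV phantom study (exact region TACs)."""
    spec = PhantomSpec(
        grid_shape=SMALL_GRID, seed=11, who_grade=4, pet_cv_at_300s=0.0, psf_fwhm_mm=0.0
    )
    return generate_study(spec)


@pytest.fixture(scope="session")
def noisy_study():
    """Small phantom study at default noise/PSF settings."""
    spec = PhantomSpec(grid_shape=SMALL_GRID, seed=5, who_grade=4)
    return generate_study(spec)
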