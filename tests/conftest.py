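import numpy as np
import pytest

from stereopol.stimgen import (
    GaussianNoise,
    OverlapMode,
    PolarityMode,
    StimulusParams,
    generate_ensemble,
)


@pytest.fixture(scope="session")
def small_params():
    """A small no-overlap mixed-polarity stimulus used across modules."""
    return StimulusParams(
        width_px=100,
        height_px=100,
        dot_size_px=4,
        density=0.1,
        overlap_mode=OverlapMode.NO_OVERLAP,
        polarity_mode=PolarityMode.MIXED,
        seed=1234,
    )


@pytest.fixture(scope="session")
def noisy_no_overlap_ensemble():
    """50 no-overlap mixed pairs with Gaussian disparity noise (zero mean
    disparity), shared by correlation tests."""
    params = StimulusParams(
        width_px=100,
        height_px=100,
        dot_size_px=4,
        density=0.4,
        overlap_mode=OverlapMode.NO_OVERLAP,
        noise_model=GaussianNoise(4.0),
        seed=7,
    )
    return generate_ensemble(params, 50)


def se_of_mean(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    return float(values.std(ddof=1) / np.sqrt(len(values)))
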