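import numpy as np
import pytest

from rppgtime import SampledSeries, UniformGrid, generate_sinusoid, sample_regular


@pytest.fixture
def grid_25hz_30s() -> UniformGrid:
    """Standard analysis grid: 30 s at a nominal 25 Hz (750 samples)."""
    return UniformGrid(0.0, 25.0, 750)


@pytest.fixture
def regular_series(grid_25hz_30s) -> SampledSeries:
    """Uncorrupted 25 Hz capture of a random resting-band sinusoid."""
    dense = generate_sinusoid(duration_s=30.0, seed=42)
    return sample_regular(dense, grid_25hz_30s)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
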