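import numpy as np
import pytest

from cortexsift import synthetic_data as syn
from cortexsift.gradients import generate_even_directions


@pytest.fixture(scope="session")
def even64():
    """64 evenly spaced directions, the standard fitting scheme."""
    return generate_even_directions(64, seed=0)


@pytest.fixture(scope="session")
def even30():
    return generate_even_directions(30, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced two-ROI benchmark dataset shared across fast tests."""
    cfg = syn.benchmark_config(n_rois=2, vertices_per_roi=60, seed=0)
    return syn.make_dataset(cfg, seed=0)
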