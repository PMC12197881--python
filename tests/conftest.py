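import numpy as np
import pytest

from chromadiff import evalstats, synth


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_rgb_pair(rng):
    """Two random 8-bit RGB images of the same size."""
    shape = (37, 23, 3)
    return (
        rng.integers(0, 256, size=shape, dtype=np.uint8),
        rng.integers(0, 256, size=shape, dtype=np.uint8),
    )


@pytest.fixture(scope="session")
def study_trio():
    """The default synthetic trio at study scale (256 x 256, seed 0)."""
    return synth.make_dataset_trio(size=256, seed=0)


@pytest.fixture(scope="session")
def study_records(study_trio):
    """Full benchmark record table for the study trio, all six metrics."""
    return evalstats.run_benchmark(study_trio)
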