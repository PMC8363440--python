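import numpy as np
import pytest

from bmptrack import PhantomConfig, generate_phantom
from bmptrack.benchmark import seeds_from_truth

# compact phantom for unit tests: same structure as the default study
# sequences, scaled down for speed
SMALL_PHANTOM = PhantomConfig(
    image_side_px=64,
    n_frames=60,
    period_frames=20,
    contraction_amplitude_px=4.0,
    ring_radius_px=20.0,
    n_spots=6,
    seed=11,
)


@pytest.fixture(scope="session")
def small_phantom():
    seq, truth = generate_phantom(SMALL_PHANTOM)
    return seq, truth, seeds_from_truth(truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
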