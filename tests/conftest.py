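import logging

import numpy as np
import pytest
from hypothesis import settings

import axonwrap as aw

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# the thresholding fallback warnings on signal-free slices are expected noise
logging.getLogger("axonwrap.segmentation").setLevel(logging.ERROR)
logging.getLogger("axonwrap.wrapping").setLevel(logging.ERROR)


@pytest.fixture
def tiny_config():
    """Noiseless 128x128 field: a 4x4 pillar grid at the assay geometry."""
    return aw.SimulationConfig(fov_shape=(128, 128), noise_sd=0.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def noiseless_field(tiny_config, rng):
    n = len(aw.pillar_centers(tiny_config))
    spec = aw.random_coverage_spec(rng, n, tiny_config.n_slices, p_full=0.4)
    stack, truths, n_nuclei = aw.generate_field(tiny_config, spec, rng=rng)
    return stack, truths, n_nuclei


def match_profiles_to_truth(profiles, regions, truths):
    """Pair each detected region/profile with the nearest ground-truth pillar."""
    pairs = []
    for region, profile in zip(regions, profiles):
        t = min(
            truths,
            key=lambda t: (t.centroid_xy[0] - region.centroid[0]) ** 2
            + (t.centroid_xy[1] - region.centroid[1]) ** 2,
        )
        pairs.append((profile, t))
    return pairs
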