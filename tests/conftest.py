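import numpy as np
import pytest
from hypothesis import settings

import hypoximap as hm

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")

# Synthetic sections are ~5x smaller than real acquisitions, so the
# rolling-ball neighbourhood scales down from 40 px accordingly.
SYNTH_SEG_PARAMS = hm.SegmentationParams(rolling_ball_radius=15)


@pytest.fixture(scope="session")
def default_specimen_run():
    """Default synthetic specimen segmented and measured once per session."""
    stack, rmask, truth = hm.generate_specimen(hm.SynthParams(seed=7))
    mask = hm.segment_nuclei(stack, "reference", SYNTH_SEG_PARAMS)
    table = hm.measure_blobs(mask, stack)
    return stack, rmask, truth, mask, table


@pytest.fixture(scope="session")
def noise_free_run():
    """Noise-free, background-free specimen for exact-identity checks."""
    params = hm.SynthParams(
        n_nuclei=60,
        n_sections=4,
        noise=hm.NoiseParams(poisson_gain=0.0, gaussian_sigma=0.0),
        background=(0.0, 0.0),
        regions=(
            hm.RegionSpec("A", (0.0, 0.5), 0.7),
            hm.RegionSpec("B", (0.5, 1.0), 1.3),
        ),
        seed=11,
    )
    stack, rmask, truth = hm.generate_specimen(params)
    mask = hm.segment_nuclei(stack, "reference", SYNTH_SEG_PARAMS)
    table = hm.measure_blobs(mask, stack)
    return stack, rmask, truth, mask, table


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
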