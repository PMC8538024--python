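import numpy as np
import pytest

from lidmetrics import eyegen, pipeline


SMALL_DIST = eyegen.DistributionConfig(mm_per_px=0.4, image_size=(256, 256),
                                       reflex_jitter_px=5.0)


@pytest.fixture(scope="session")
def small_dataset():
    """30-subject cohort at reduced resolution, shared across test modules."""
    return eyegen.generate_dataset(30, SMALL_DIST, seed=101)


@pytest.fixture(scope="session")
def small_patches(small_dataset):
    primary, merged, exclusions = pipeline.build_patches(small_dataset)
    return primary, merged, exclusions


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
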