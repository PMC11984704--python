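import numpy as np
import pytest

from tractbmi import (
    AtlasVolume,
    FAVolume,
    GeneratorConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """40-subject matrix-mode cohort with 2 planted columns (fast shared fixture)."""
    cfg = GeneratorConfig(
        n_nw=20, n_ob=20, n_tracts=4, n_planted=2, noise_sd=0.01, seed=11
    )
    return generate_cohort(cfg)


@pytest.fixture
def toy_atlas():
    """8x8x8 atlas with two 2x2x2 tracts on a zero background."""
    labels = np.zeros((8, 8, 8), dtype=np.int64)
    labels[1:3, 1:3, 1:3] = 1
    labels[5:7, 5:7, 5:7] = 2
    return AtlasVolume(labels, {1: "tract A", 2: "tract B"})


@pytest.fixture
def toy_volume_factory():
    def make(seed=0, shape=(8, 8, 8), subject_id="sub-0000"):
        rng = np.random.default_rng(seed)
        return FAVolume(rng.uniform(0, 1, size=shape), subject_id=subject_id)

    return make
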