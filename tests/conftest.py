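import numpy as np
import pytest

from tauscreen import (
    SegmentationParams,
    SynthFieldConfig,
    generate_field,
    segment_field,
)

#: field size used throughout the unit tests: large enough for a dense
#: culture at the default morphology, small enough to segment in <1 s
TEST_SHAPE = (512, 512)


@pytest.fixture(scope="session")
def default_config():
    return SynthFieldConfig(grid_shape=TEST_SHAPE, n_neurons=30,
                            n_nonneuronal=10, n_dead=5, seed=3)


@pytest.fixture(scope="session")
def default_field(default_config):
    """One synthetic field with ground truth at default SNR."""
    return generate_field(default_config)


@pytest.fixture(scope="session")
def default_masks(default_field):
    field, _ = default_field
    return segment_field(field, SegmentationParams())


@pytest.fixture(scope="session")
def noise_field():
    """A field with no cells at all: pure background noise."""
    cfg = SynthFieldConfig(grid_shape=TEST_SHAPE, n_neurons=0,
                           n_nonneuronal=0, n_dead=0, seed=17)
    return generate_field(cfg)
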