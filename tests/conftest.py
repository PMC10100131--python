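import numpy as np
import pytest

from gliomap import synth


@pytest.fixture(scope="session")
def space16():
    return synth.make_brain_space(dims=(16, 16, 16), voxel_size=(2, 2, 2),
                                  n_regions=8, seed=0)


@pytest.fixture(scope="session")
def space24():
    return synth.make_brain_space(dims=(24, 24, 24), voxel_size=(2, 2, 2),
                                  n_regions=30, seed=0)


@pytest.fixture(scope="session")
def space32():
    return synth.make_brain_space(dims=(32, 32, 32), voxel_size=(2, 2, 2),
                                  n_regions=60, seed=0)


@pytest.fixture(scope="session")
def field16(space16):
    return synth.make_occurrence_field(space16, n_foci=2, autocorr_length=8,
                                       seed=1)


@pytest.fixture(scope="session")
def cohort16(space16, field16):
    cfg = synth.SimulationConfig(n_gbm=40, n_lgg=20, seed=5,
                                 volume_lognormal=(0.0, 0.4))
    return synth.sample_cohort(space16, field16, field16, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
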