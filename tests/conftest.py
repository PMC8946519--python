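import numpy as np
import pytest

from eafcn import (BrainVolume, CohortSpec, SubjectRecord, build_network,
                   fcn_spec_default, normalize_intensity, simulate_cohort)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def desk_model():
    """A randomly initialized desk-profile FCN (attention-free)."""
    return build_network(fcn_spec_default("desk"), seed=42)


@pytest.fixture(scope="session")
def tiny_cohort():
    """10+10 subjects on 48^3 volumes: the smallest grid admitting 47^3 patches."""
    spec = CohortSpec(n_ad=10, n_nc=10, volume_shape=(48, 48, 48),
                      lesion_centers=((20, 20, 20),), lesion_radius=8.0, seed=7)
    return [(rec, normalize_intensity(vol)) for rec, vol in simulate_cohort(spec)]


@pytest.fixture
def random_volume(rng):
    return BrainVolume(rng.random((55, 55, 55), dtype=np.float32), "rand55", normalized=True)


def make_record(sid="s0", label="NC", age=75.0, sex="F", mmse=28):
    return SubjectRecord(subject_id=sid, label=label, age=age, sex=sex, mmse=mmse)
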