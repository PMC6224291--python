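import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hippostim.geometry import (DielectricTable, RegionLabel,
                                SyntheticAnatomyParams, VoxelVolume,
                                generate_synthetic_dentate)

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_anatomy():
    return SyntheticAnatomyParams.small()


@pytest.fixture(scope="session")
def small_volume(small_anatomy):
    return generate_synthetic_dentate(small_anatomy)


@pytest.fixture(scope="session")
def default_volume():
    return generate_synthetic_dentate(SyntheticAnatomyParams())


@pytest.fixture(scope="session")
def dielectrics():
    return DielectricTable.default()


@pytest.fixture()
def homogeneous_cube():
    """A single-label cube (no bath) for solver oracles."""
    def make(n=24, label=RegionLabel.MOLECULAR_MIDDLE):
        labels = np.full((n, n, n), int(label), np.uint8)
        return VoxelVolume(labels, 12.0)
    return make
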