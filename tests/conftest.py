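import numpy as np
import pytest

from sldecode.volumes import AnalysisMask, VolumeGrid
from sldecode.synthetic import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def grid8():
    return VolumeGrid.isotropic((8, 8, 6), 3.0)


@pytest.fixture(scope="session")
def box_mask(grid8):
    data = np.zeros(grid8.shape, dtype=bool)
    data[1:7, 1:7, 1:5] = True
    return AnalysisMask(data, grid8, provenance="test box")


@pytest.fixture(scope="session")
def tiny_cohort(grid8):
    """Small signal cohort shared by read-only tests (9+9, strong effect)."""
    cfg = SyntheticCohortConfig(
        n_per_group=9,
        grid=grid8,
        roi_center_mm=(0.0, 0.0, 0.0),
        roi_radius_mm=6.0,
        effect_size=2.0,
        pattern_seed=101,
        noise_seed=102,
        behavior_seed=103,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
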