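import numpy as np
import pytest

from hypoconn.mica import ComponentSet
from hypoconn.synthetic import generate_study
from hypoconn.types import VolumeGeometry


@pytest.fixture(scope="session")
def small_study():
    """3 sessions, K=2, small grid — fast shared fixture for null-ish tests."""
    return generate_study(n_sessions=3, K=2, geometry=VolumeGeometry(shape=(12, 12, 10)),
                          mask_shape_spec={"kind": "ellipsoid", "radii_vox": (3.2, 3.2, 2.4)},
                          n_timepoints=60, seed=11)



def truth_component_set(dataset) -> ComponentSet:
    """ComponentSet built from the simulator's planted maps (z-scaled)."""
    M = dataset.truth.component_maps
    Mz = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, keepdims=True)
    return ComponentSet(d=M.shape[0], spatial_maps=Mz, timecourses=None,
                        mask=dataset.mask, voxel_index=np.argwhere(dataset.mask))
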