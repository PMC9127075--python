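import numpy as np
import pytest

from menitrack.acquisition import generate_direction_scheme
from menitrack.phantom import (
    PhantomSpec,
    ground_truth_zone_labels,
    make_crescent_mask,
    make_tensor_field,
    synthesize_dwi,
)
from menitrack.tensor_fit import compute_scalar_maps, fit_dti


@pytest.fixture(scope="session")
def protocol_scheme():
    """Default protocol scheme: 81 half-sphere directions + 8 b0, b = 1000."""
    return generate_direction_scheme(81, 8, 1000.0, seed=1)


@pytest.fixture(scope="session")
def small_scheme():
    """Cheap 24-direction scheme for fit tests."""
    return generate_direction_scheme(24, 2, 1000.0, seed=3, max_iter=400)


@pytest.fixture(scope="session")
def phantom48():
    """Noise-free 48³ crescent phantom with zone-dependent tensors."""
    spec = PhantomSpec(grid_shape=(48, 48, 48), seed=2)
    mask = make_crescent_mask(spec)
    gt_zones = ground_truth_zone_labels(mask, spec)
    tensors = make_tensor_field(mask, spec, zone_labels=gt_zones)
    return {"spec": spec, "mask": mask, "gt_zones": gt_zones, "tensors": tensors}


@pytest.fixture(scope="session")
def phantom48_maps(phantom48):
    """Scalar maps of the ground-truth tensor field."""
    return compute_scalar_maps(phantom48["tensors"])


@pytest.fixture(scope="session")
def fitted48(phantom48, small_scheme):
    """Noise-free DWI synthesis + WLS tensor fit on the 48³ phantom."""
    spec, mask = phantom48["spec"], phantom48["mask"]
    dwi = synthesize_dwi(phantom48["tensors"], small_scheme, spec)
    tensors = fit_dti(dwi, small_scheme, mask, method="wls")
    tensors.affine = spec.affine
    return {"dwi": dwi, "tensors": tensors, "maps": compute_scalar_maps(tensors)}


@pytest.fixture(scope="session")
def annulus128():
    """Half-annulus mask, inner 10 / outer 25 voxels, height 10, 128³ grid."""
    spec = PhantomSpec(
        grid_shape=(128, 128, 128),
        voxel_size=1.0,
        inner_radius=10.0,
        outer_radius=25.0,
        height=10.0,
    )
    return spec, make_crescent_mask(spec)


def assert_partition(parcellation, mask):
    """Labels cover exactly the mask, each voxel once."""
    assert np.array_equal(parcellation.support, np.asarray(mask, dtype=bool))
    assert sum(parcellation.counts().values()) == int(np.count_nonzero(mask))
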