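import numpy as np
import pytest

from conftest import assert_partition
from menitrack.errors import DegenerateGeometryError, ParameterError
from menitrack.parcellation import (
    PART_NAMES,
    ZONE_NAMES,
    Parcellation,
    combine_parcellations,
    fit_rotation_frame,
    radial_segmentation,
    rotational_segmentation,
)
from menitrack.phantom import PhantomSpec, make_crescent_mask


def _arc_mask(grid, inner, outer, height, arc_center_deg, arc_half_deg):
    """Half-annulus with the arc centered at an arbitrary in-plane angle."""
    c = (np.asarray(grid, dtype=float) - 1) / 2
    ii = np.indices(grid).astype(float)
    dx, dy, dz = ii[0] - c[0], ii[1] - c[1], ii[2] - c[2]
    r = np.hypot(dx, dy)
    phi = np.degrees(np.arctan2(dy, dx))
    dphi = (phi - arc_center_deg + 180) % 360 - 180
    return (
        (r >= inner) & (r <= outer) & (np.abs(dphi) <= arc_half_deg) & (np.abs(dz) <= height / 2)
    )


@pytest.fixture(scope="module")
def frame128(annulus128):
    _, mask = annulus128
    return fit_rotation_frame(mask)


class TestFitRotationFrame:
    def test_center_recovery(self, annulus128, frame128):
        spec, _ = annulus128
        true_center = np.asarray(spec.center) / spec.voxel_size
        assert np.linalg.norm(frame128.center - true_center) < 1.0

    def test_normal_is_z(self, frame128):
        assert abs(abs(frame128.normal[2]) - 1.0) < 1e-6

    def test_zero_axis_centers_the_arc(self, frame128):
        lo, hi = frame128.angle_range
        assert abs(lo + hi) < 2.0  # extent centered on 0 deg
        assert abs(abs(frame128.zero_axis[0]) - 1.0) < 0.02  # arc faces +x

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_rotation_frame(np.zeros((8, 8, 8), dtype=bool))

    def test_collinear_cloud_rejected(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[:, 10, 10] = True
        with pytest.raises(DegenerateGeometryError):
            fit_rotation_frame(mask)

    def test_full_ring_flagged_ambiguous(self):
        spec = PhantomSpec(grid_shape=(64, 64, 64), voxel_size=1.0,
                           inner_radius=10.0, outer_radius=25.0, height=8.0, arc_span=360.0)
        mask = make_crescent_mask(spec)
        frame = fit_rotation_frame(mask)
        assert frame.ambiguous
        true_center = np.asarray(spec.center)
        assert np.linalg.norm(frame.center - true_center) < 1.0

    def test_equivariance_under_30_degree_arc_shift(self):
        # analytic ground truth: same crescent with the arc centered at 30 deg
        grid = (96, 96, 32)
        m0 = _arc_mask(grid, 12, 30, 8, 0.0, 90.0)
        m30 = _arc_mask(grid, 12, 30, 8, 30.0, 90.0)
        f0, f30 = fit_rotation_frame(m0), fit_rotation_frame(m30)
        ang = np.degrees(np.arctan2(f30.zero_axis[1], f30.zero_axis[0]))
        assert abs(abs(ang) - 30.0) < 2.0
        z0 = radial_segmentation(m0, f0)
        z30 = radial_segmentation(m30, f30)
        c0, c30 = z0.counts(), z30.counts()
        for code in (1, 2, 3):
            assert c30[code] == pytest.approx(c0[code], rel=0.02)


class TestRadialSegmentation:
    def test_partition(self, annulus128, frame128):
        _, mask = annulus128
        parc = radial_segmentation(mask, frame128)
        assert_partition(parc, mask)

    def test_analytic_trisection_fractions(self, annulus128, frame128):
        # annulus areas: (15^2-10^2):(20^2-15^2):(25^2-20^2) = 23.8 : 33.3 : 42.9 %
        _, mask = annulus128
        parc = radial_segmentation(mask, frame128)
        n = mask.sum()
        fractions = {c: 100.0 * v / n for c, v in parc.counts().items()}
        assert fractions[1] == pytest.approx(23.81, abs=1.5)
        assert fractions[2] == pytest.approx(33.33, abs=1.5)
        assert fractions[3] == pytest.approx(42.86, abs=1.5)

    def test_single_zone_identity(self, annulus128, frame128):
        _, mask = annulus128
        parc = radial_segmentation(mask, frame128, n_zones=1)
        assert np.array_equal(parc.labels > 0, mask)
        assert set(np.unique(parc.labels[mask])) == {1}

    def test_zone_names_and_radial_ordering(self, annulus128, frame128):
        _, mask = annulus128
        parc = radial_segmentation(mask, frame128)
        assert [parc.table[c]["zone"] for c in parc.codes] == list(ZONE_NAMES)
        pts = np.argwhere(mask).astype(float)
        _, r = frame128.polar_coordinates(pts)
        labels = parc.labels[mask]
        means = [r[labels == c].mean() for c in (1, 2, 3)]
        assert means[0] < means[1] < means[2]  # W-W < R-W < R-R

    def test_invalid_step(self, annulus128, frame128):
        _, mask = annulus128
        with pytest.raises(ParameterError):
            radial_segmentation(mask, frame128, step=0.0)

    def test_equivariance_under_90_degree_grid_rotation(self):
        spec = PhantomSpec(grid_shape=(64, 64, 64), voxel_size=1.0,
                           inner_radius=8.0, outer_radius=20.0, height=8.0)
        mask = make_crescent_mask(spec)
        rot = np.rot90(mask, k=1, axes=(0, 1))
        z = radial_segmentation(mask, fit_rotation_frame(mask))
        z_rot = radial_segmentation(rot, fit_rotation_frame(rot))
        agree = np.mean(np.rot90(z.labels, k=1, axes=(0, 1)) == z_rot.labels)
        assert agree > 0.999


class TestRotationalSegmentation:
    def test_partition_and_names(self, annulus128, frame128):
        _, mask = annulus128
        parc = rotational_segmentation(mask, frame128)
        assert_partition(parc, mask)
        assert [parc.table[c]["part"] for c in parc.codes] == list(PART_NAMES)

    def test_zero_angle_voxel_is_body(self, annulus128, frame128):
        _, mask = annulus128
        parc = rotational_segmentation(mask, frame128, body_span=60.0)
        pts = np.argwhere(mask).astype(float)
        phi, _ = frame128.polar_coordinates(pts)
        at_zero = np.abs(phi) < 1.0
        assert np.all(parc.labels[mask][at_zero] == 2)

    def test_body_fraction_on_half_annulus(self, annulus128, frame128):
        # uniform angular measure: 60/180 of the voxels fall in the body
        _, mask = annulus128
        parc = rotational_segmentation(mask, frame128, body_span=60.0)
        frac = 100.0 * parc.counts()[2] / mask.sum()
        assert frac == pytest.approx(33.33, abs=1.5)

    def test_full_span_all_body(self, annulus128, frame128):
        _, mask = annulus128
        parc = rotational_segmentation(mask, frame128, body_span=181.0)
        assert np.all(parc.labels[mask] == 2)

    def test_invalid_span(self, annulus128, frame128):
        _, mask = annulus128
        with pytest.raises(ParameterError):
            rotational_segmentation(mask, frame128, body_span=0.0)


class TestCombineParcellations:
    def test_nine_labels(self, annulus128, frame128):
        _, mask = annulus128
        zones = radial_segmentation(mask, frame128)
        parts = rotational_segmentation(mask, frame128)
        combined = combine_parcellations(zones, parts)
        assert_partition(combined, mask)
        present = set(np.unique(combined.labels[mask]))
        assert present == set(range(1, 10))
        # code layout: part-major, zone-minor
        assert combined.table[1] == {"zone": "W-W", "part": "anterior"}
        assert combined.table[9] == {"zone": "R-R", "part": "posterior"}

    def test_single_zone_input_reduces_to_parts(self, annulus128, frame128):
        _, mask = annulus128
        zones = radial_segmentation(mask, frame128, n_zones=1)
        parts = rotational_segmentation(mask, frame128)
        combined = combine_parcellations(zones, parts)
        assert np.array_equal(combined.labels, parts.labels)
        assert [combined.table[c]["part"] for c in combined.codes] == list(PART_NAMES)

    def test_support_mismatch_rejected(self, annulus128, frame128):
        _, mask = annulus128
        zones = radial_segmentation(mask, frame128)
        parts = rotational_segmentation(mask, frame128)
        bad = Parcellation(np.zeros_like(parts.labels), parts.table)
        with pytest.raises(ParameterError):
            combine_parcellations(zones, bad)
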