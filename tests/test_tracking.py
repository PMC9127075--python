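import numpy as np
import pytest

from menitrack.errors import ParameterError, StreamlineFormatError
from menitrack.phantom import (
    PhantomSpec,
    TensorField,
    make_crescent_mask,
    make_tensor_field,
)
from menitrack.tensor_fit import compute_scalar_maps
from menitrack.tracking import (
    StreamlineSet,
    TrackingParams,
    read_streamlines,
    track_streamlines,
    write_streamlines,
)


def _uniform_field(shape, e1, lams=(1.7e-3, 0.3e-3, 0.3e-3)):
    """Constant tensor field with principal direction e1 everywhere."""
    e1 = np.asarray(e1, dtype=float)
    e1 /= np.linalg.norm(e1)
    # complete an orthonormal basis
    helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    D = lams[0] * np.outer(e1, e1) + lams[1] * np.outer(e2, e2) + lams[2] * np.outer(e3, e3)
    d = np.empty(shape + (6,))
    d[...] = [D[0, 0], D[0, 1], D[0, 2], D[1, 1], D[1, 2], D[2, 2]]
    return TensorField(d, np.ones(shape, dtype=bool))


class TestTrackingParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"angle_threshold": 0.0},
            {"angle_threshold": 95.0},
            {"step_size": -1.0},
            {"fa_threshold": 1.5},
            {"seeds_per_voxel": 0},
            {"max_length": 0.0},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ParameterError):
            TrackingParams(**kwargs)


class TestTrackStreamlines:
    def test_straight_field_spans_box(self):
        shape = (20, 20, 20)
        tensors = _uniform_field(shape, [1.0, 0.0, 0.0])
        maps = compute_scalar_maps(tensors)
        mask = np.ones(shape, dtype=bool)
        params = TrackingParams(step_size=0.5)
        sset = track_streamlines(tensors, maps, mask, params)
        # pick the streamline seeded at the box center
        centered = [s for s, seed in zip(sset.streamlines, sset.seeds)
                    if np.allclose(seed, [10, 10, 10])]
        line = centered[0]
        length = np.linalg.norm(np.diff(line, axis=0), axis=1).sum()
        assert length == pytest.approx(19.0, abs=1.0)  # box extent +/- one step
        assert np.ptp(line[:, 1]) < 1e-9 and np.ptp(line[:, 2]) < 1e-9

    def test_90_degree_interface_terminates(self):
        # two half-volumes with orthogonal eigenvectors: 90 deg > 45 deg rule
        shape = (20, 20, 20)
        left = _uniform_field(shape, [1.0, 0.0, 0.0]).data
        right = _uniform_field(shape, [0.0, 1.0, 0.0]).data
        d = np.where(np.arange(shape[0])[:, None, None, None] < 10, left, right)
        tensors = TensorField(d, np.ones(shape, dtype=bool))
        maps = compute_scalar_maps(tensors)
        params = TrackingParams(step_size=0.5)
        sset = track_streamlines(tensors, maps, np.ones(shape, dtype=bool), params,
                                 max_seeds=300)
        for line in sset.streamlines:
            # no streamline crosses the interface at x = 9.5 by more than a step
            assert (line[:, 0].max() < 10.6) or (line[:, 0].min() > 9.4)

    def test_circumferential_radius_preserved(self, phantom48, phantom48_maps):
        # geometric oracle: points stay near their seed radius on an annulus
        spec = phantom48["spec"]
        sset = track_streamlines(
            phantom48["tensors"], phantom48_maps, phantom48["mask"],
            TrackingParams(rng_seed=1), max_seeds=200,
        )
        assert len(sset) > 100
        c = np.asarray(spec.center)
        long_enough = 0
        for line, seed in zip(sset.streamlines, sset.seeds):
            r = np.hypot(line[:, 0] - c[0], line[:, 1] - c[1])
            r_seed = np.hypot(seed[0] - c[0], seed[1] - c[1])
            assert np.abs(r - r_seed).max() / r_seed < 0.05
            if line.shape[0] > 30:
                long_enough += 1
                # best-fit circle radius of a long streamline matches seed radius
                r_fit = r.mean()
                assert r_fit == pytest.approx(r_seed, rel=0.05)
        assert long_enough > 10

    def test_step_spacing_invariant(self, phantom48, phantom48_maps):
        sset = track_streamlines(
            phantom48["tensors"], phantom48_maps, phantom48["mask"],
            TrackingParams(rng_seed=1), max_seeds=50,
        )
        for line in sset.streamlines:
            spacing = np.linalg.norm(np.diff(line, axis=0), axis=1)
            assert np.allclose(spacing, sset.step_size, atol=1e-6)

    def test_determinism(self, phantom48, phantom48_maps):
        kwargs = dict(params=TrackingParams(seeds_per_voxel=2, rng_seed=5), max_seeds=100)
        a = track_streamlines(phantom48["tensors"], phantom48_maps, phantom48["mask"], **kwargs)
        b = track_streamlines(phantom48["tensors"], phantom48_maps, phantom48["mask"], **kwargs)
        assert len(a) == len(b)
        for s, t in zip(a.streamlines, b.streamlines):
            assert np.array_equal(s, t)

    def test_antipodal_invariance(self, phantom48, phantom48_maps):
        # tensors are quadratic in the eigenvectors: flipping every
        # eigenvector reconstructs the identical field, hence identical tracks
        spec, mask = phantom48["spec"], phantom48["mask"]
        t1 = phantom48["tensors"]
        mats = t1.as_matrices()[t1.valid]
        evals, evecs = np.linalg.eigh(mats)
        rebuilt = np.einsum("vij,vj,vkj->vik", -evecs, evals, -evecs)
        d2 = np.zeros_like(t1.data)
        d2[t1.valid] = np.stack(
            [rebuilt[:, 0, 0], rebuilt[:, 0, 1], rebuilt[:, 0, 2],
             rebuilt[:, 1, 1], rebuilt[:, 1, 2], rebuilt[:, 2, 2]], axis=-1,
        )
        t2 = TensorField(d2, t1.valid, t1.affine)
        a = track_streamlines(t1, phantom48_maps, mask, TrackingParams(), max_seeds=50)
        b = track_streamlines(t2, phantom48_maps, mask, TrackingParams(), max_seeds=50)
        for s, t in zip(a.streamlines, b.streamlines):
            assert np.allclose(s, t, atol=1e-9)

    def test_points_stay_near_mask(self, phantom48, phantom48_maps):
        spec, mask = phantom48["spec"], phantom48["mask"]
        from scipy.ndimage import binary_dilation

        dilated = binary_dilation(mask, iterations=1)
        inv = np.linalg.inv(spec.affine)
        sset = track_streamlines(phantom48["tensors"], phantom48_maps, mask,
                                 TrackingParams(rng_seed=0), max_seeds=100)
        for line in sset.streamlines:
            vox = np.rint(line @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            assert np.all(dilated[vox[:, 0], vox[:, 1], vox[:, 2]])

    def test_mixed_pattern_has_both_families(self):
        # radial wedge inside a circumferential field: both tract families
        spec = PhantomSpec(grid_shape=(48, 48, 48), fiber_pattern="mixed",
                           radial_wedge=(0.0, 20.0), seed=4)
        mask = make_crescent_mask(spec)
        tensors = make_tensor_field(mask, spec)
        maps = compute_scalar_maps(tensors)
        sset = track_streamlines(tensors, maps, mask, TrackingParams(rng_seed=4),
                                 max_seeds=400)
        c = np.asarray(spec.center)
        radial_like = circ_like = 0
        for line in sset.streamlines:
            if line.shape[0] < 5:
                continue
            d = line[-1] - line[0]
            d /= np.linalg.norm(d)
            mid = line[line.shape[0] // 2]
            u = mid[:2] - c[:2]
            u /= np.linalg.norm(u)
            along_radius = abs(d[0] * u[0] + d[1] * u[1])
            if along_radius > 0.8:
                radial_like += 1
            elif along_radius < 0.2:
                circ_like += 1
        assert radial_like > 10 and circ_like > 10

    def test_empty_mask(self, phantom48, phantom48_maps):
        empty = np.zeros_like(phantom48["mask"])
        sset = track_streamlines(phantom48["tensors"], phantom48_maps, empty,
                                 TrackingParams())
        assert len(sset) == 0

    def test_min_length_filter(self, phantom48, phantom48_maps):
        long_only = track_streamlines(
            phantom48["tensors"], phantom48_maps, phantom48["mask"],
            TrackingParams(min_length=2.0, rng_seed=1), max_seeds=200,
        )
        assert np.all(long_only.lengths() >= 2.0 - 1e-9)


@pytest.fixture(scope="module")
def sample(phantom48, phantom48_maps):
    return track_streamlines(phantom48["tensors"], phantom48_maps,
                             phantom48["mask"], TrackingParams(rng_seed=2),
                             max_seeds=50)


class TestStreamlineIO:
    @pytest.mark.parametrize("ext", ["trk", "tck"])
    def test_round_trip(self, tmp_path, sample, ext):
        path = tmp_path / f"tracts.{ext}"
        write_streamlines(sample, path)
        back = read_streamlines(path)
        assert len(back) == len(sample)
        for a, b in zip(sample.streamlines, back.streamlines):
            assert np.allclose(a, b, atol=1e-4)

    def test_empty_round_trip(self, tmp_path):
        empty = StreamlineSet([], np.empty((0, 3)), np.eye(4), 0.5)
        path = tmp_path / "empty.trk"
        write_streamlines(empty, path)
        back = read_streamlines(path)
        assert len(back) == 0

    def test_header_count_consistency(self, tmp_path, sample):
        import nibabel as nib

        path = tmp_path / "tracts.trk"
        write_streamlines(sample, path)
        trk = nib.streamlines.load(str(path), lazy_load=True)
        assert int(trk.header["nb_streamlines"]) == len(sample)

    def test_unsupported_extension(self, tmp_path, sample):
        with pytest.raises(StreamlineFormatError):
            write_streamlines(sample, tmp_path / "tracts.xyz")

    def test_malformed_file(self, tmp_path):
        bad = tmp_path / "bad.trk"
        bad.write_bytes(b"not a streamline file at all")
        with pytest.raises(StreamlineFormatError):
            read_streamlines(bad)
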