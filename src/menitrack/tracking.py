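"""Deterministic streamline tractography along the principal eigenvector.

Fixed-step integration (midpoint by default; plain Euler available),
bidirectional from every seed, with sign continuity of the eigenvector and
termination on mask exit, low FA, a turning angle above threshold (default
45°), or maximum length.  Tensor components are interpolated trilinearly
and eigen-decomposed at the interpolated point, avoiding eigenvector-sign
interpolation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from nibabel.streamlines import TckFile, Tractogram, TrkFile

from .errors import ParameterError, StreamlineFormatError


@dataclass
class TrackingParams:
    """Tractography parameters.

    ``step_size`` defaults to half the voxel size when None.  Lengths in mm.
    """

    angle_threshold: float = 45.0
    step_size: float | None = None
    fa_threshold: float = 0.05
    seeds_per_voxel: int = 1
    min_length: float = 0.0
    max_length: float = 100.0
    rng_seed: int = 0
    integrator: str = "rk2"  # rk2 (midpoint) | euler

    def __post_init__(self):
        if self.integrator not in ("rk2", "euler"):
            raise ParameterError(f"unknown integrator {self.integrator!r}")
        if not 0 < self.angle_threshold < 90:
            raise ParameterError("angle_threshold must lie in (0, 90) degrees")
        if self.step_size is not None and self.step_size <= 0:
            raise ParameterError("step_size must be positive")
        if not 0 <= self.fa_threshold < 1:
            raise ParameterError("fa_threshold must lie in [0, 1)")
        if self.seeds_per_voxel < 1:
            raise ParameterError("seeds_per_voxel must be >= 1")
        if self.min_length < 0 or self.max_length <= 0:
            raise ParameterError("length bounds must be positive")


@dataclass
class StreamlineSet:
    """Polylines in world coordinates (mm) with seed provenance."""

    streamlines: list  # list of (k, 3) float arrays
    seeds: np.ndarray  # (n, 3) world seed point per streamline
    affine: np.ndarray  # voxel -> world of the source grid
    step_size: float

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        """Arc length per streamline, mm."""
        return np.array(
            [np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in self.streamlines]
        )


def _trilinear(volume: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of grid + (C,) data at continuous voxel coords."""
    shape = np.asarray(volume.shape[:3])
    p = np.clip(pts, 0.0, shape - 1.000001)
    i0 = np.floor(p).astype(int)
    f = p - i0
    out = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                vals = volume[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
                out = out + w[:, None] * vals if vals.ndim > 1 else out + w * vals
    return out


def _principal_directions(tensor_data: np.ndarray, pts_vox: np.ndarray) -> np.ndarray:
    d = _trilinear(tensor_data, pts_vox)  # (n, 6)
    m = np.empty((len(d), 3, 3))
    m[:, 0, 0] = d[:, 0]
    m[:, 0, 1] = m[:, 1, 0] = d[:, 1]
    m[:, 0, 2] = m[:, 2, 0] = d[:, 2]
    m[:, 1, 1] = d[:, 3]
    m[:, 1, 2] = m[:, 2, 1] = d[:, 4]
    m[:, 2, 2] = d[:, 5]
    _, evecs = np.linalg.eigh(m)
    return evecs[:, :, 2]  # largest eigenvalue


def _in_mask(mask: np.ndarray, pts_vox: np.ndarray) -> np.ndarray:
    idx = np.rint(pts_vox).astype(int)
    shape = np.asarray(mask.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    ok = np.zeros(len(pts_vox), dtype=bool)
    if inside.any():
        ii = idx[inside]
        ok[inside] = mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    return ok


def _propagate(tensor_data, fa_vol, mask, seeds_world, init_dirs, inv_affine, step, params):
    """Grow one direction branch from every seed; returns per-seed point lists."""
    n = len(seeds_world)
    max_steps = int(np.ceil(params.max_length / step)) if np.isfinite(params.max_length) else 4000
    max_steps = min(max_steps, 100000)
    cos_thr = np.cos(np.radians(params.angle_threshold))

    pts = seeds_world.copy()
    prev = init_dirs.copy()
    alive = np.ones(n, dtype=bool)
    n_steps = np.zeros(n, dtype=int)
    history = np.full((max_steps, n, 3), np.nan, dtype=np.float64)

    for k in range(max_steps):
        if not alive.any():
            break
        ai = np.flatnonzero(alive)
        p = pts[ai]
        pv = _world_to_vox(inv_affine, p)
        v = _principal_directions(tensor_data, pv)
        # sign continuity: keep positive dot with the previous step
        dots = np.sum(v * prev[ai], axis=1)
        v[dots < 0] *= -1
        if params.integrator == "rk2":
            # midpoint re-evaluation kills the outward spiral of plain Euler
            # on curved fields while preserving the fixed step length
            mid = p + 0.5 * step * v
            v2 = _principal_directions(tensor_data, _world_to_vox(inv_affine, mid))
            flip = np.sum(v2 * v, axis=1) < 0
            v2[flip] *= -1
            v = v2
            dots = np.sum(v * prev[ai], axis=1)
            v[dots < 0] *= -1
        dots = np.abs(np.sum(v * prev[ai], axis=1))
        turn_ok = dots >= cos_thr

        nxt = p + step * v
        nv = _world_to_vox(inv_affine, nxt)
        mask_ok = _in_mask(mask, nv)
        fa_ok = np.zeros(len(ai), dtype=bool)
        if mask_ok.any():
            fa_vals = _trilinear(fa_vol, nv[mask_ok])
            fa_ok[mask_ok] = fa_vals >= params.fa_threshold
        keep = turn_ok & mask_ok & fa_ok

        ki = ai[keep]
        pts[ki] = nxt[keep]
        prev[ki] = v[keep]
        history[k, ki] = nxt[keep]
        n_steps[ki] = k + 1
        alive[ai[~keep]] = False

    return [history[: n_steps[i], i] for i in range(n)]


def _world_to_vox(inv_affine: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return pts @ inv_affine[:3, :3].T + inv_affine[:3, 3]


def track_streamlines(
    tensors,
    scalar_maps,
    mask: np.ndarray,
    params: TrackingParams | None = None,
    affine: np.ndarray | None = None,
    max_seeds: int | None = None,
) -> StreamlineSet:
    """Whole-mask deterministic tractography.

    Seeds are placed at every in-mask voxel center (plus seeded jitter for
    ``seeds_per_voxel > 1``); each seed grows bidirectionally along the
    interpolated principal eigenvector.  ``max_seeds`` subsamples seeds
    deterministically (evenly over the mask) to bound runtime.  Streamlines
    shorter than ``min_length`` or with fewer than 2 points are dropped.
    """
    params = params or TrackingParams()
    mask = np.asarray(mask, dtype=bool)
    if affine is None:
        affine = getattr(tensors, "affine", np.eye(4))
    inv_affine = np.linalg.inv(affine)
    voxel_size = float(np.mean(np.linalg.norm(affine[:3, :3], axis=0)))
    step = params.step_size if params.step_size is not None else 0.5 * voxel_size

    vox = np.argwhere(mask).astype(float)
    if vox.shape[0] == 0:
        return StreamlineSet([], np.empty((0, 3)), affine, step)
    if max_seeds is not None and vox.shape[0] > max_seeds:
        sel = np.linspace(0, vox.shape[0] - 1, max_seeds).astype(int)
        vox = vox[sel]

    seeds_vox = [vox]
    if params.seeds_per_voxel > 1:
        rng = np.random.default_rng(params.rng_seed)
        for _ in range(params.seeds_per_voxel - 1):
            seeds_vox.append(vox + rng.uniform(-0.5, 0.5, vox.shape))
    seeds_vox = np.vstack(seeds_vox)
    seeds_world = seeds_vox @ affine[:3, :3].T + affine[:3, 3]

    fa_vol = np.nan_to_num(scalar_maps.fa, nan=0.0)
    tensor_data = tensors.data

    # drop seeds below the FA threshold outright
    seed_fa = _trilinear(fa_vol, _world_to_vox(inv_affine, seeds_world))
    good = seed_fa >= params.fa_threshold
    seeds_world = seeds_world[good]
    if len(seeds_world) == 0:
        return StreamlineSet([], np.empty((0, 3)), affine, step)

    d0 = _principal_directions(tensor_data, _world_to_vox(inv_affine, seeds_world))
    half_len = params.max_length / 2.0
    half = TrackingParams(
        angle_threshold=params.angle_threshold,
        step_size=step,
        fa_threshold=params.fa_threshold,
        seeds_per_voxel=1,
        min_length=0.0,
        max_length=half_len,
        rng_seed=params.rng_seed,
        integrator=params.integrator,
    )
    fwd = _propagate(tensor_data, fa_vol, mask, seeds_world, d0, inv_affine, step, half)
    bwd = _propagate(tensor_data, fa_vol, mask, seeds_world, -d0, inv_affine, step, half)

    streamlines, kept_seeds = [], []
    for i, seed in enumerate(seeds_world):
        line = np.vstack([bwd[i][::-1], seed[None, :], fwd[i]])
        if line.shape[0] < 2:
            continue
        if (line.shape[0] - 1) * step < params.min_length:
            continue
        streamlines.append(line)
        kept_seeds.append(seed)
    kept = np.asarray(kept_seeds) if kept_seeds else np.empty((0, 3))
    return StreamlineSet(streamlines, kept, affine, step)


def write_streamlines(sset: StreamlineSet, path) -> None:
    """Serialize to a TrackVis-style (.trk) or plain (.tck) container."""
    path = str(path)
    tractogram = Tractogram(
        [s.astype(np.float32) for s in sset.streamlines], affine_to_rasmm=np.eye(4)
    )
    if path.endswith(".trk"):
        header = {
            "voxel_to_rasmm": sset.affine.astype(np.float32),
            "voxel_sizes": np.linalg.norm(sset.affine[:3, :3], axis=0).astype(np.float32),
            "dimensions": np.array([1, 1, 1], dtype=np.int16),
            "voxel_order": "RAS",
        }
        TrkFile(tractogram, header).save(path)
    elif path.endswith(".tck"):
        TckFile(tractogram).save(path)
    else:
        raise StreamlineFormatError(f"unsupported streamline container: {path}")


def read_streamlines(path) -> StreamlineSet:
    """Load a .trk/.tck container back into a StreamlineSet (world mm)."""
    path = str(path)
    try:
        obj = nib.streamlines.load(path)
    except Exception as exc:  # nibabel raises assorted errors on bad headers
        raise StreamlineFormatError(f"cannot read streamline file {path}: {exc}") from exc
    streamlines = [np.asarray(s, dtype=float) for s in obj.streamlines]
    if hasattr(obj.header, "get"):
        aff = obj.header.get("voxel_to_rasmm", np.eye(4))
    else:
        aff = np.eye(4)
    aff = np.asarray(aff, dtype=float)
    if not np.all(np.isfinite(aff)) or abs(np.linalg.det(aff[:3, :3])) < 1e-12:
        aff = np.eye(4)
    if streamlines:
        steps = np.linalg.norm(np.diff(streamlines[0], axis=0), axis=1)
        step = float(np.median(steps)) if steps.size else 0.0
    else:
        step = 0.0
    seeds = np.array([s[0] for s in streamlines]) if streamlines else np.empty((0, 3))
    return StreamlineSet(streamlines, seeds, aff, step)
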