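"""Automatic parcellation of a C-shaped binary mask.

Divides the mask into radial zones (W-W / R-W / R-R, inner to outer),
rotational parts (anterior / body / posterior) and their combination,
using per-voxel polar coordinates about a fitted rotation frame.  Voxel
angle binning is the resampling-free limit of rotating the mask in small
angular steps and slicing it at the central plane.

All geometry is computed in voxel index coordinates; isotropic voxels are
assumed (anisotropic grids would skew the circle fit).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import DegenerateGeometryError, ParameterError

logger = logging.getLogger(__name__)

ZONE_NAMES = ("W-W", "R-W", "R-R")  # inner third -> outer third
PART_NAMES = ("anterior", "body", "posterior")

#: wedges with fewer voxels than this borrow radial bounds from neighbors
SPARSE_WEDGE_MIN_VOXELS = 10


@dataclass(frozen=True)
class RotationFrame:
    """In-plane rotation frame of a C-shaped mask.

    ``zero_axis`` is the 0° direction (the "central plane" normal direction
    in-plane); polar angles are measured from it, positive about ``normal``.
    """

    center: np.ndarray  # (3,) voxel coordinates
    normal: np.ndarray  # (3,) unit rotation axis
    zero_axis: np.ndarray  # (3,) unit 0° direction, perpendicular to normal
    angle_range: tuple  # (min_deg, max_deg) angular extent of the mask
    ambiguous: bool = False  # True when the 0° direction is ill-defined (full ring)

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        z = np.asarray(self.zero_axis, dtype=float)
        if abs(np.linalg.norm(n) - 1) > 1e-9 or abs(np.linalg.norm(z) - 1) > 1e-9:
            raise ParameterError("normal and zero_axis must be unit vectors")
        if abs(float(n @ z)) > 1e-9:
            raise ParameterError("zero_axis must be perpendicular to normal")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "zero_axis", z)

    @property
    def in_plane_second_axis(self) -> np.ndarray:
        """Unit vector completing the right-handed in-plane basis (90° direction)."""
        return np.cross(self.normal, self.zero_axis)

    def polar_coordinates(self, points: np.ndarray):
        """Polar angle (degrees, in (-180, 180]) and in-plane radius of points."""
        w = np.atleast_2d(points) - self.center
        u = w @ self.zero_axis
        v = w @ self.in_plane_second_axis
        phi = np.degrees(np.arctan2(v, u))
        r = np.hypot(u, v)
        return phi, r


@dataclass
class Parcellation:
    """Integer label volume plus a table mapping codes to (zone, part) names."""

    labels: np.ndarray  # integer label volume, 0 = background
    table: dict  # code -> {"zone": str|None, "part": str|None}

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ParameterError("label volume must be integer-typed")
        self.table = {int(k): dict(v) for k, v in self.table.items()}

    @property
    def codes(self) -> list:
        return sorted(self.table)

    @property
    def support(self) -> np.ndarray:
        return self.labels > 0

    def counts(self) -> dict:
        """Voxel count per label code."""
        return {c: int(np.count_nonzero(self.labels == c)) for c in self.codes}

    def write_table(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({str(k): v for k, v in self.table.items()}, fh, indent=2)

    @classmethod
    def read_table(cls, labels: np.ndarray, path) -> "Parcellation":
        with open(path) as fh:
            table = {int(k): v for k, v in json.load(fh).items()}
        return cls(labels, table)


def _kasa_circle_fit(u: np.ndarray, v: np.ndarray):
    """Algebraic (Kåsa) least-squares circle fit; returns (uc, vc, radius)."""
    A = np.column_stack([2 * u, 2 * v, np.ones_like(u)])
    rhs = u**2 + v**2
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    uc, vc, c = sol
    radius = float(np.sqrt(max(c + uc**2 + vc**2, 0.0)))
    return float(uc), float(vc), radius


def _fit_annulus_center(u: np.ndarray, v: np.ndarray, bin_deg: float = 5.0, n_iter: int = 30):
    """Rotation center of a solid annular point cloud in plane coordinates.

    A plain Kåsa fit on a solid partial annulus is biased toward the arc;
    instead, iterate: bin points by polar angle about the current center,
    reduce each bin to its radial midpoint (midpoints converge to the true
    mid-circle, where the algebraic fit is exact), refit, repeat.
    """
    uc, vc = float(u.mean()), float(v.mean())
    for _ in range(n_iter):
        du, dv = u - uc, v - vc
        ang = np.arctan2(dv, du)
        r = np.hypot(du, dv)
        edges = np.arange(ang.min(), ang.max() + 1e-9, np.radians(bin_deg))
        if edges.size < 4:  # tiny angular extent; keep the plain fit
            break
        which = np.clip(np.digitize(ang, edges) - 1, 0, edges.size - 2)
        mid_u, mid_v = [], []
        for b in range(edges.size - 1):
            sel = which == b
            if np.count_nonzero(sel) < 5:
                continue
            rm = (r[sel].min() + r[sel].max()) / 2.0
            am = np.arctan2(dv[sel].mean(), du[sel].mean())
            mid_u.append(uc + rm * np.cos(am))
            mid_v.append(vc + rm * np.sin(am))
        if len(mid_u) < 3:
            break
        uc_new, vc_new, _ = _kasa_circle_fit(np.asarray(mid_u), np.asarray(mid_v))
        shift = np.hypot(uc_new - uc, vc_new - vc)
        uc, vc = uc_new, vc_new
        if shift < 1e-6:
            break
    return uc, vc


def fit_rotation_frame(mask: np.ndarray) -> RotationFrame:
    """Fit the rotation frame of a C-shaped mask.

    The dominant plane is spanned by the first two principal axes of the
    in-mask voxel coordinates; the rotation center is an iteratively
    debiased circle fit of the coordinates projected onto that plane; the
    0° direction points at the circular mean of the in-mask polar angles,
    so the mask's angular extent is centered on 0°.  For (near-)full rings
    the 0° direction is ill-defined and flagged ``ambiguous``.

    Raises
    ------
    DegenerateGeometryError
        On an empty mask or a voxel cloud without in-plane extent.
    """
    pts = np.argwhere(np.asarray(mask, dtype=bool)).astype(float)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("mask has fewer than 3 voxels")
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] <= 1e-9 * max(evals[2], 1.0):
        raise DegenerateGeometryError("voxel cloud is collinear")
    normal = evecs[:, 0]
    a1, a2 = evecs[:, 2], evecs[:, 1]
    # right-handed basis, normal sign fixed for reproducibility
    if np.cross(a1, a2) @ normal < 0:
        normal = -normal
    if normal[np.argmax(np.abs(normal))] < 0:
        normal, a2 = -normal, -a2

    w = pts - centroid
    uc, vc = _fit_annulus_center(w @ a1, w @ a2)
    center = centroid + uc * a1 + vc * a2

    w = pts - center
    alpha = np.arctan2(w @ a2, w @ a1)
    resultant = np.array([np.cos(alpha).mean(), np.sin(alpha).mean()])
    rlen = float(np.linalg.norm(resultant))
    ambiguous = rlen < 0.05
    if ambiguous:
        zero_axis = a2 - (a2 @ normal) * normal
        zero_axis /= np.linalg.norm(zero_axis)
        logger.warning("angular mass is uniform; zero_axis is ambiguous")
    else:
        mu = float(np.arctan2(resultant[1], resultant[0]))
        zero_axis = np.cos(mu) * a1 + np.sin(mu) * a2
        zero_axis /= np.linalg.norm(zero_axis)

    frame = RotationFrame(center, normal, zero_axis, (0.0, 0.0), ambiguous)
    phi, _ = frame.polar_coordinates(pts)
    return RotationFrame(
        center, normal, zero_axis, (float(phi.min()), float(phi.max())), ambiguous
    )


def _fill_sparse_bounds(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Interpolate per-wedge bounds across sparse/empty wedges."""
    out = values.astype(float).copy()
    idx = np.arange(values.size)
    if not valid.any():
        raise DegenerateGeometryError("all wedges are sparse; cannot infer radial bounds")
    out[~valid] = np.interp(idx[~valid], idx[valid], values[valid])
    return out


def radial_segmentation(
    mask: np.ndarray,
    frame: RotationFrame,
    step: float = 0.5,
    n_zones: int = 3,
) -> Parcellation:
    """Trisect (by default) the mask into radial zones, wedge by wedge.

    Every in-mask voxel is assigned to the angular wedge of width `step`
    degrees containing its polar angle; within each wedge the radial
    extent of the wedge's own voxels is divided into `n_zones` equal-length
    intervals.  Inner to outer, zones are W-W, R-W, R-R (codes 1..3).
    Wedges with fewer than 10 voxels borrow bounds from neighbors.
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    if n_zones < 1:
        raise ParameterError("n_zones must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int16)
    pts = np.argwhere(mask).astype(float)
    if pts.shape[0] == 0:
        raise DegenerateGeometryError("empty mask")

    if n_zones == 3:
        table = {i + 1: {"zone": ZONE_NAMES[i], "part": None} for i in range(3)}
    else:
        table = {i + 1: {"zone": f"zone_{i + 1}", "part": None} for i in range(n_zones)}
    if n_zones == 1:
        labels[mask] = 1
        return Parcellation(labels, table)

    phi, r = frame.polar_coordinates(pts)
    lo, hi = frame.angle_range
    # clamp stray voxels outside the fitted range into the covered wedges
    n_stray = int(np.count_nonzero((phi < lo) | (phi > hi)))
    if n_stray:
        logger.info("clamping %d voxels outside the fitted angle range", n_stray)
    phi = np.clip(phi, lo, hi)
    n_wedges = max(int(np.ceil((hi - lo) / step)), 1)
    wedge = np.minimum(((phi - lo) / step).astype(int), n_wedges - 1)

    r_min = np.full(n_wedges, np.nan)
    r_max = np.full(n_wedges, np.nan)
    counts = np.bincount(wedge, minlength=n_wedges)
    order = np.argsort(wedge, kind="stable")
    bounds = np.searchsorted(wedge[order], np.arange(n_wedges + 1))
    for w in range(n_wedges):
        sel = order[bounds[w] : bounds[w + 1]]
        if sel.size:
            r_min[w] = r[sel].min()
            r_max[w] = r[sel].max()
    valid = counts >= SPARSE_WEDGE_MIN_VOXELS
    if not valid.all():
        logger.info(
            "interpolating radial bounds for %d sparse wedge(s)",
            int(np.count_nonzero(~valid)),
        )
        r_min = _fill_sparse_bounds(np.where(valid, r_min, 0.0), valid)
        r_max = _fill_sparse_bounds(np.where(valid, r_max, 0.0), valid)

    # wedges thinner than the voxel spacing undersample the radial extent;
    # pool bounds over a window spanning ~2 voxels of arc at the median radius
    arc_deg_per_wedge = step * np.radians(1.0) * float(np.median(r))
    window = max(1, int(np.ceil(2.0 / max(arc_deg_per_wedge, 1e-9))))
    if window > 1:
        window = min(window, n_wedges)
        r_min = ndi.minimum_filter1d(r_min, size=window, mode="nearest")
        r_max = ndi.maximum_filter1d(r_max, size=window, mode="nearest")

    width = np.maximum(r_max - r_min, 1e-12) / n_zones
    zone = ((r - r_min[wedge]) / width[wedge]).astype(int)
    zone = np.clip(zone, 0, n_zones - 1)
    labels[tuple(pts.astype(int).T)] = zone + 1
    return Parcellation(labels, table)


def rotational_segmentation(
    mask: np.ndarray,
    frame: RotationFrame,
    body_span: float = 60.0,
) -> Parcellation:
    """Split the mask into anterior / body / posterior parts by polar angle.

    The body covers angles in [-body_span/2, +body_span/2); anterior lies
    below, posterior at or above.  Codes: anterior=1, body=2, posterior=3.
    """
    if body_span <= 0:
        raise ParameterError("body_span must be positive")
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask).astype(float)
    if pts.shape[0] == 0:
        raise DegenerateGeometryError("empty mask")
    phi, _ = frame.polar_coordinates(pts)
    half = body_span / 2.0
    part = np.where(phi < -half, 0, np.where(phi < half, 1, 2))
    labels = np.zeros(mask.shape, dtype=np.int16)
    labels[tuple(pts.astype(int).T)] = part + 1
    table = {i + 1: {"zone": None, "part": PART_NAMES[i]} for i in range(3)}
    return Parcellation(labels, table)


def combine_parcellations(zones: Parcellation, parts: Parcellation) -> Parcellation:
    """Intersect a zonal and a rotational parcellation into one label volume.

    Output code = n_zones·(part index) + zone index + 1, so with 3 zones and
    3 parts the 9 codes run (anterior: W-W, R-W, R-R), (body: ...), ....
    """
    if zones.labels.shape != parts.labels.shape:
        raise ParameterError("parcellations are on different grids")
    if not np.array_equal(zones.support, parts.support):
        raise ParameterError("parcellations do not share mask support")

    zone_codes = zones.codes
    part_codes = parts.codes
    nz = len(zone_codes)
    zone_idx = {c: i for i, c in enumerate(zone_codes)}
    part_idx = {c: i for i, c in enumerate(part_codes)}

    labels = np.zeros(zones.labels.shape, dtype=np.int16)
    table = {}
    sup = zones.support
    zl = zones.labels[sup]
    pl = parts.labels[sup]
    zi = np.vectorize(zone_idx.get)(zl)
    pi = np.vectorize(part_idx.get)(pl)
    labels[sup] = nz * pi + zi + 1
    for pc in part_codes:
        for zc in zone_codes:
            code = nz * part_idx[pc] + zone_idx[zc] + 1
            table[code] = {
                "zone": zones.table[zc]["zone"],
                "part": parts.table[pc]["part"],
            }
    return Parcellation(labels, table)
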