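"""Synthetic crescent phantoms: masks, fibrous tensor fields, noisy DWI.

The default phantom is a half-annulus (C-shaped) solid with circumferential
primary fibers and zone-dependent diffusivities rising in anisotropy from
the inner to the outer third, mimicking meniscal fibrocartilage.  One seed
in the spec governs all stochastic steps via independent substreams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, PhantomSpecError
from .parcellation import PART_NAMES, ZONE_NAMES, Parcellation

#: Default per-zone (λ1, λ2, λ3) in mm²/s, inner (W-W) to outer (R-R).
#: Axial/radial diffusivities follow reported porcine meniscus zonal values,
#: with the two minor eigenvalues both set to the radial diffusivity.
DEFAULT_ZONE_EIGENVALUES = (
    (1.17e-3, 1.00e-3, 1.00e-3),  # W-W (inner third)
    (1.09e-3, 0.83e-3, 0.83e-3),  # R-W (middle third)
    (0.97e-3, 0.70e-3, 0.70e-3),  # R-R (outer third)
)

_RNG_MASK, _RNG_FIBER, _RNG_NOISE, _RNG_SEED_JITTER = range(4)


@dataclass
class PhantomSpec:
    """Geometry, tissue and acquisition-noise parameters of a crescent phantom.

    Lengths are in mm; ``arc_span`` in degrees (180 = half annulus), centered
    on the +x axis.  ``snr`` is S0/σ on b0 (``np.inf`` = noise-free).
    ``taper`` linearly shrinks the slab height from the inner to the outer
    radius (0 = uniform thickness, 0.5 = outer height is half the inner).
    """

    grid_shape: tuple = (64, 64, 64)
    voxel_size: float = 0.125
    center: tuple | None = None  # mm; default: grid center
    inner_radius: float | None = None  # default: 0.4 x outer_radius
    outer_radius: float | None = None  # default: 0.79 x in-plane half extent
    arc_span: float = 180.0
    height: float | None = None  # default: 10 voxels
    zone_eigenvalues: tuple = DEFAULT_ZONE_EIGENVALUES
    fiber_pattern: str = "circumferential"  # circumferential | radial | mixed
    radial_wedge: tuple = (0.0, 15.0)  # mixed pattern: (center°, half-width°)
    angular_jitter_deg: float = 0.0
    taper: float = 0.0
    S0: float = 1000.0
    snr: float = np.inf
    seed: int = 0

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise PhantomSpecError("voxel_size must be positive")
        half_extent = (min(self.grid_shape[:2]) - 1) / 2 * self.voxel_size
        if self.outer_radius is None:
            self.outer_radius = 0.79 * half_extent
        if self.inner_radius is None:
            self.inner_radius = 0.4 * self.outer_radius
        if self.height is None:
            self.height = 10 * self.voxel_size
        if not 0 < self.inner_radius < self.outer_radius:
            raise PhantomSpecError("need 0 < inner_radius < outer_radius")
        if not 0 < self.arc_span <= 360:
            raise PhantomSpecError("arc_span must lie in (0, 360]")
        if self.height <= 0:
            raise PhantomSpecError("height must be positive")
        if not 0 <= self.taper < 1:
            raise PhantomSpecError("taper must lie in [0, 1)")
        for lam in self.zone_eigenvalues:
            l1, l2, l3 = lam
            if not (l1 >= l2 >= l3 > 0):
                raise PhantomSpecError("zone eigenvalues must satisfy λ1 >= λ2 >= λ3 > 0")
        if self.fiber_pattern not in ("circumferential", "radial", "mixed"):
            raise PhantomSpecError(f"unknown fiber pattern {self.fiber_pattern!r}")
        if self.center is None:
            self.center = tuple(
                (np.asarray(self.grid_shape, dtype=float) - 1) / 2 * self.voxel_size
            )

    @property
    def affine(self) -> np.ndarray:
        """RAS affine: world = voxel index × voxel_size (origin at index 0)."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def _world_coords(self):
        idx = [np.arange(n, dtype=float) * self.voxel_size for n in self.grid_shape]
        return np.meshgrid(*idx, indexing="ij")


def _cylindrical(spec: PhantomSpec):
    x, y, z = spec._world_coords()
    cx, cy, cz = spec.center
    dx, dy, dz = x - cx, y - cy, z - cz
    r = np.hypot(dx, dy)
    phi = np.degrees(np.arctan2(dy, dx))
    return r, phi, dz


def make_crescent_mask(spec: PhantomSpec) -> np.ndarray:
    """Voxel-center membership test for the crescent solid (deterministic).

    A voxel is inside iff its center lies within [inner_radius, outer_radius]
    radially, within ±arc_span/2 of the +x axis angularly, and within the
    (possibly tapered) height slab.
    """
    half_extent = np.min(
        [
            np.min(spec.center[:2]),
            np.min(
                (np.asarray(spec.grid_shape[:2]) - 1) * spec.voxel_size
                - np.asarray(spec.center[:2])
            ),
        ]
    )
    if spec.outer_radius > half_extent + spec.voxel_size / 2:
        raise PhantomSpecError("outer_radius exceeds the grid extent from the center")
    r, phi, dz = _cylindrical(spec)
    radial = (r >= spec.inner_radius) & (r <= spec.outer_radius)
    if spec.arc_span >= 360:
        angular = np.ones_like(radial)
    else:
        angular = np.abs(phi) <= spec.arc_span / 2
    frac = np.clip(
        (r - spec.inner_radius) / (spec.outer_radius - spec.inner_radius), 0, 1
    )
    local_height = spec.height * (1 - spec.taper * frac)
    axial = np.abs(dz) <= local_height / 2
    return radial & angular & axial


def ground_truth_zone_labels(mask: np.ndarray, spec: PhantomSpec) -> Parcellation:
    """Exact radial trisection of [inner_radius, outer_radius] (W-W/R-W/R-R)."""
    r, _, _ = _cylindrical(spec)
    width = (spec.outer_radius - spec.inner_radius) / 3
    zone = np.clip(((r - spec.inner_radius) / width).astype(int), 0, 2)
    labels = np.where(mask, zone + 1, 0).astype(np.int16)
    table = {i + 1: {"zone": ZONE_NAMES[i], "part": None} for i in range(3)}
    return Parcellation(labels, table)


def ground_truth_part_labels(
    mask: np.ndarray, spec: PhantomSpec, body_span: float = 60.0
) -> Parcellation:
    """Exact angular split into anterior / body / posterior parts."""
    _, phi, _ = _cylindrical(spec)
    half = body_span / 2
    part = np.where(phi < -half, 0, np.where(phi < half, 1, 2))
    labels = np.where(mask, part + 1, 0).astype(np.int16)
    table = {i + 1: {"zone": None, "part": PART_NAMES[i]} for i in range(3)}
    return Parcellation(labels, table)


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor, six unique components.

    ``data`` has shape grid + (6,), component order
    (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz), mm²/s.  ``valid`` marks voxels where
    the tensor is defined.
    """

    data: np.ndarray
    valid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.shape[:-1] != self.valid.shape or self.data.shape[-1] != 6:
            raise ParameterError("tensor data must have shape grid + (6,)")

    def as_matrices(self) -> np.ndarray:
        """Full symmetric 3×3 matrices, shape grid + (3, 3)."""
        d = self.data
        m = np.empty(d.shape[:-1] + (3, 3))
        m[..., 0, 0] = d[..., 0]
        m[..., 0, 1] = m[..., 1, 0] = d[..., 1]
        m[..., 0, 2] = m[..., 2, 0] = d[..., 2]
        m[..., 1, 1] = d[..., 3]
        m[..., 1, 2] = m[..., 2, 1] = d[..., 4]
        m[..., 2, 2] = d[..., 5]
        return m

    @classmethod
    def from_matrices(cls, m: np.ndarray, valid: np.ndarray, affine=None) -> "TensorField":
        d = np.stack(
            [m[..., 0, 0], m[..., 0, 1], m[..., 0, 2], m[..., 1, 1], m[..., 1, 2], m[..., 2, 2]],
            axis=-1,
        )
        return cls(d, valid, np.eye(4) if affine is None else affine)


def make_tensor_field(
    mask: np.ndarray,
    spec: PhantomSpec,
    zone_labels: Parcellation | None = None,
) -> TensorField:
    """Assemble R·diag(λ)·Rᵀ tensors with the spec's fiber pattern.

    The principal eigenvector is the local circumferential tangent
    (``circumferential``), the outward radial direction (``radial``), or
    circumferential with radial fibers inside ``spec.radial_wedge``
    (``mixed``).  Eigenvalues come from the voxel's zone (ground-truth
    trisection if no parcellation is given, or a single triple if only one
    is configured).  Voxels at zero radius are excluded with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterError("mask is empty")
    r, phi, _ = _cylindrical(spec)

    at_center = mask & (r < 1e-12)
    if at_center.any():
        warnings.warn(
            f"excluding {int(at_center.sum())} voxel(s) at zero radius from the tensor field"
        )
        mask = mask & ~at_center

    zone_lams = np.asarray(spec.zone_eigenvalues, dtype=float)
    if zone_labels is not None:
        zone_idx = np.clip(zone_labels.labels - 1, 0, len(zone_lams) - 1)
    elif len(zone_lams) == 1:
        zone_idx = np.zeros(mask.shape, dtype=int)
    elif len(zone_lams) == 3:
        zone_idx = ground_truth_zone_labels(mask, spec).labels - 1
        zone_idx = np.clip(zone_idx, 0, 2)
    else:
        raise ParameterError("provide zone_labels for non-standard zone counts")

    ii = np.argwhere(mask)
    phi_v = np.radians(phi[mask])
    radial_dir = np.stack([np.cos(phi_v), np.sin(phi_v), np.zeros_like(phi_v)], axis=1)
    circ_dir = np.stack([-np.sin(phi_v), np.cos(phi_v), np.zeros_like(phi_v)], axis=1)

    if spec.fiber_pattern == "circumferential":
        use_radial = np.zeros(len(ii), dtype=bool)
    elif spec.fiber_pattern == "radial":
        use_radial = np.ones(len(ii), dtype=bool)
    else:  # mixed: radial fibers inside the configured wedge
        wc, hw = spec.radial_wedge
        dphi = (np.degrees(phi_v) - wc + 180) % 360 - 180
        use_radial = np.abs(dphi) <= hw

    e1 = np.where(use_radial[:, None], radial_dir, circ_dir)
    e2 = np.where(use_radial[:, None], circ_dir, radial_dir)
    e3 = np.zeros_like(e1)
    e3[:, 2] = 1.0

    if spec.angular_jitter_deg > 0:
        rng = spec.rng(_RNG_FIBER)
        theta = np.radians(rng.normal(0.0, spec.angular_jitter_deg, len(ii)))
        c, s = np.cos(theta)[:, None], np.sin(theta)[:, None]
        e1, e2 = c * e1 + s * e2, -s * e1 + c * e2

    lam = zone_lams[zone_idx[mask]]
    mats = (
        lam[:, 0, None, None] * e1[:, :, None] * e1[:, None, :]
        + lam[:, 1, None, None] * e2[:, :, None] * e2[:, None, :]
        + lam[:, 2, None, None] * e3[:, :, None] * e3[:, None, :]
    )
    data = np.zeros(mask.shape + (6,))
    sel = tuple(ii.T)
    data[sel + (0,)] = mats[:, 0, 0]
    data[sel + (1,)] = mats[:, 0, 1]
    data[sel + (2,)] = mats[:, 0, 2]
    data[sel + (3,)] = mats[:, 1, 1]
    data[sel + (4,)] = mats[:, 1, 2]
    data[sel + (5,)] = mats[:, 2, 2]
    return TensorField(data, mask, spec.affine)


def add_rician_noise(volume: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Rician-corrupt a magnitude volume: sqrt((v + n1)² + n2²), n ~ N(0, σ)."""
    if sigma < 0:
        raise ParameterError("sigma must be non-negative")
    volume = np.asarray(volume, dtype=float)
    if sigma == 0:
        return volume.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, volume.shape)
    n2 = rng.normal(0.0, sigma, volume.shape)
    return np.sqrt((volume + n1) ** 2 + n2**2)


def synthesize_dwi(tensors: TensorField, scheme, spec: PhantomSpec) -> np.ndarray:
    """Forward-simulate the DWI series: S = S0·exp(−b·gᵀDg) plus Rician noise.

    Out-of-mask voxels are zero.  Noise is applied only for finite
    ``spec.snr`` with σ = S0/snr, seeded from the spec's noise substream.
    """
    mask = tensors.valid
    d = tensors.data[mask]  # (nvox, 6)
    g = scheme.directions
    b = scheme.b_values
    # quadratic form gᵀDg from the six unique components
    quad = (
        g[:, 0] ** 2 * d[:, None, 0]
        + g[:, 1] ** 2 * d[:, None, 3]
        + g[:, 2] ** 2 * d[:, None, 5]
        + 2 * g[:, 0] * g[:, 1] * d[:, None, 1]
        + 2 * g[:, 0] * g[:, 2] * d[:, None, 2]
        + 2 * g[:, 1] * g[:, 2] * d[:, None, 4]
    )  # (nvox, nvol)
    signal = spec.S0 * np.exp(-b[None, :] * quad)
    out = np.zeros(mask.shape + (scheme.n_volumes,))
    out[mask] = signal
    if np.isfinite(spec.snr):
        sigma = spec.S0 / spec.snr
        noise_seed = spec.rng(_RNG_NOISE).integers(2**31)
        noisy = add_rician_noise(out, sigma, seed=int(noise_seed))
        noisy[~mask] = 0.0
        out = noisy
    return out
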