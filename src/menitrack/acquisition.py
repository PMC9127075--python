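"""Diffusion gradient schemes: generation, physics, and FSL-dialect I/O.

A scheme is the per-volume list of diffusion weightings (b-values, s/mm²)
and unit encoding directions.  Directions live in the image coordinate
frame, the convention of the two-file bval/bvec dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GradientTableFormatError, InvalidSchemeError

#: Gyromagnetic ratio of the proton, rad s^-1 T^-1.
GYROMAGNETIC_RATIO = 2.6752218744e8

#: Protocol preset: 81 half-sphere directions, 8 b0 volumes, b = 1000 s/mm².
PROTOCOL_N_DIRECTIONS = 81
PROTOCOL_N_B0 = 8
PROTOCOL_B_VALUE = 1000.0

_DIR_NORM_TOL = 1e-6


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume diffusion weightings and unit encoding directions.

    Parameters
    ----------
    b_values : (n,) array
        Diffusion weighting per volume, s/mm².  Entries flagged b0 are 0.
    directions : (n, 3) array
        Unit encoding direction per volume; (0, 0, 0) for b0 entries.
    """

    b_values: np.ndarray
    directions: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float).ravel()
        g = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if g.shape != (b.size, 3):
            raise InvalidSchemeError(
                f"directions shape {g.shape} does not match {b.size} b-values"
            )
        if np.any(b < 0):
            raise InvalidSchemeError("b-values must be non-negative")
        dwi = b > 0
        norms = np.linalg.norm(g[dwi], axis=1)
        if dwi.any() and np.any(np.abs(norms - 1.0) > _DIR_NORM_TOL):
            raise InvalidSchemeError("diffusion-weighted directions must be unit norm")
        if np.any(np.linalg.norm(g[~dwi], axis=1) > _DIR_NORM_TOL):
            raise InvalidSchemeError("b0 entries must have zero direction")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    @property
    def b0_mask(self) -> np.ndarray:
        """Boolean flag per volume, True where b = 0."""
        return self.b_values == 0

    @property
    def n_volumes(self) -> int:
        return self.b_values.size

    @property
    def n_directions(self) -> int:
        return int(np.count_nonzero(~self.b0_mask))

    def __eq__(self, other) -> bool:
        if not isinstance(other, GradientScheme):
            return NotImplemented
        return np.allclose(self.b_values, other.b_values) and np.allclose(
            self.directions, other.directions, atol=_DIR_NORM_TOL
        )


def antipodal_energy(directions: np.ndarray) -> float:
    """Electrostatic energy of a direction set under antipodal symmetry.

    Sum over unordered pairs i < j of 1/‖gi − gj‖ + 1/‖gi + gj‖, i.e. every
    direction interacts with both copies (±g) of every other direction.
    """
    g = np.asarray(directions, dtype=float)
    n = g.shape[0]
    if n < 2:
        return 0.0
    diff = g[:, None, :] - g[None, :, :]
    summ = g[:, None, :] + g[None, :, :]
    dd = np.linalg.norm(diff, axis=-1)
    ds = np.linalg.norm(summ, axis=-1)
    iu = np.triu_indices(n, k=1)
    return float(np.sum(1.0 / dd[iu]) + np.sum(1.0 / ds[iu]))


def _energy_gradient(g: np.ndarray) -> np.ndarray:
    n = g.shape[0]
    diff = g[:, None, :] - g[None, :, :]
    summ = g[:, None, :] + g[None, :, :]
    dd = np.linalg.norm(diff, axis=-1)
    ds = np.linalg.norm(summ, axis=-1)
    np.fill_diagonal(dd, np.inf)
    np.fill_diagonal(ds, np.inf)
    grad = -np.sum(diff / dd[..., None] ** 3, axis=1)
    grad -= np.sum(summ / ds[..., None] ** 3, axis=1)
    return grad


def optimize_half_sphere_directions(
    n_dirs: int,
    seed: int = 0,
    max_iter: int = 1000,
    return_energies: bool = False,
):
    """Distribute `n_dirs` unit vectors uniformly over a half sphere.

    Minimizes the antipodally-symmetric electrostatic energy by projected
    gradient descent with backtracking from a seeded random start.  The
    energy is non-increasing across accepted iterations; the result is
    deterministic for a fixed seed.  Final directions are flipped into the
    z ≥ 0 hemisphere (the energy is antipodally invariant).
    """
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_dirs, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)

    energies = [antipodal_energy(g)]
    if n_dirs > 1:
        step = 0.1
        for _ in range(max_iter):
            grad = _energy_gradient(g)
            # project onto the tangent space of the sphere
            grad -= np.sum(grad * g, axis=1, keepdims=True) * g
            gnorm = np.linalg.norm(grad)
            if gnorm < 1e-12:
                break
            trial = g - step * grad
            trial /= np.linalg.norm(trial, axis=1, keepdims=True)
            e_trial = antipodal_energy(trial)
            if e_trial <= energies[-1]:
                g = trial
                energies.append(e_trial)
                step = min(step * 1.1, 1.0)
            else:
                step *= 0.5
                if step < 1e-14:
                    break

    flip = g[:, 2] < 0
    g[flip] *= -1.0
    if return_energies:
        return g, np.asarray(energies)
    return g


def generate_direction_scheme(
    n_dirs: int,
    n_b0: int = 0,
    b_value: float = PROTOCOL_B_VALUE,
    seed: int = 0,
    max_iter: int = 1000,
) -> GradientScheme:
    """Build a single-shell scheme with uniform half-sphere directions.

    `n_b0` zero-weighted entries are prepended to the `n_dirs` optimized
    directions.  Deterministic for a fixed seed.

    Raises
    ------
    InvalidSchemeError
        If ``n_dirs == 0`` while ``b_value > 0``, or counts are negative.
    """
    if n_dirs == 0 and b_value > 0:
        raise InvalidSchemeError("cannot build a diffusion-weighted scheme with 0 directions")
    if n_dirs < 0 or n_b0 < 0:
        raise InvalidSchemeError("direction and b0 counts must be non-negative")
    if b_value < 0:
        raise InvalidSchemeError("b-value must be non-negative")

    dirs = optimize_half_sphere_directions(n_dirs, seed=seed, max_iter=max_iter)
    b = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b_value))])
    g = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(b, g)


def paper_protocol_scheme(seed: int = 0) -> GradientScheme:
    """Default protocol preset: 81 directions + 8 b0 at b = 1000 s/mm²."""
    return generate_direction_scheme(
        PROTOCOL_N_DIRECTIONS, PROTOCOL_N_B0, PROTOCOL_B_VALUE, seed=seed
    )


def stejskal_tanner_b(
    G: float, delta: float, Delta: float, gamma: float = GYROMAGNETIC_RATIO
) -> float:
    """b-value (s/mm²) of a pulsed-gradient spin-echo experiment.

    b = γ² G² δ² (Δ − δ/3), computed in SI (s/m²) then converted to s/mm².

    Parameters
    ----------
    G : gradient amplitude, T/m
    delta : gradient duration δ, s
    Delta : gradient separation Δ, s
    gamma : gyromagnetic ratio, rad s⁻¹ T⁻¹
    """
    if G < 0 or delta < 0 or Delta < 0 or gamma < 0:
        raise ValueError("all Stejskal-Tanner arguments must be non-negative")
    if Delta < delta / 3.0:
        raise ValueError("gradient separation must satisfy Delta >= delta/3")
    b_si = gamma**2 * G**2 * delta**2 * (Delta - delta / 3.0)  # s/m²
    return b_si * 1e-6


def gradient_amplitude_for_b(
    b: float, delta: float, Delta: float, gamma: float = GYROMAGNETIC_RATIO
) -> float:
    """Invert the Stejskal-Tanner relation for the gradient amplitude (T/m)."""
    if b < 0 or delta <= 0 or Delta < delta / 3.0 or gamma <= 0:
        raise ValueError("invalid Stejskal-Tanner parameters")
    return float(np.sqrt(b * 1e6 / (gamma**2 * delta**2 * (Delta - delta / 3.0))))


def write_gradient_table(scheme: GradientScheme, bval_path, bvec_path) -> None:
    """Write the two-file (bval/bvec) gradient table, one volume per column."""
    np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.6f")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.6f")


def read_gradient_table(bval_path, bvec_path, b0_threshold: float = 10.0) -> GradientScheme:
    """Read a two-file gradient table.

    Entries with b below `b0_threshold` (s/mm²) are treated as b0: their
    b-value is zeroed and their direction set to (0, 0, 0).  Non-b0
    directions are renormalized to unit length.

    Raises
    ------
    GradientTableFormatError
        On a row-count other than 1 (bval) / 3 (bvec) or a column mismatch.
    """
    bval = np.atleast_2d(np.loadtxt(bval_path, dtype=float))
    bvec = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bval.shape[0] != 1:
        raise GradientTableFormatError(
            f"{bval_path}: expected a single row of b-values, got {bval.shape[0]} rows"
        )
    if bvec.shape[0] != 3:
        raise GradientTableFormatError(
            f"{bvec_path}: expected 3 direction rows, got {bvec.shape[0]}"
        )
    if bval.shape[1] != bvec.shape[1]:
        raise GradientTableFormatError(
            f"column mismatch: {bval.shape[1]} b-values vs {bvec.shape[1]} directions"
        )
    b = bval.ravel().copy()
    g = bvec.T.copy()
    is_b0 = b < b0_threshold
    b[is_b0] = 0.0
    g[is_b0] = 0.0
    norms = np.linalg.norm(g[~is_b0], axis=1)
    if np.any(norms == 0):
        raise GradientTableFormatError("zero direction with b above the b0 threshold")
    g[~is_b0] /= norms[:, None]
    return GradientScheme(b, g)
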