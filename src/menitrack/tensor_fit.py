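"""Voxelwise diffusion tensor estimation and scalar map computation.

The tensor is fit by linear least squares on the log signal,
ln S = ln S0 − b·gᵀDg, with an optional second weighted pass (weights =
squared predicted signal).  Scalar maps (FA, MD, AD, RD, color-FA) come
from the per-voxel eigen-decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientSchemeError, ParameterError
from .phantom import TensorField

# QC flag bits
QC_LOG_CLAMP = 1  # non-positive signal floored before the log
QC_NEGATIVE_EIGENVALUE = 2  # eigenvalue clamped to zero in metric computation
QC_SINGULAR_FIT = 4  # per-voxel design was singular; tensor invalid


@dataclass
class ScalarMaps:
    """Rotation-invariant tensor metrics plus the principal eigenvector.

    FA is dimensionless in [0, 1]; MD/AD/RD in mm²/s.  ``color_fa`` is
    |e1| scaled by FA.  ``qc`` is a bitmask volume (see QC_* constants).
    Out-of-mask voxels are NaN in the float maps.
    """

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    color_fa: np.ndarray
    e1: np.ndarray  # principal eigenvector field, grid + (3,)
    eigenvalues: np.ndarray  # sorted descending, grid + (3,)
    qc: np.ndarray
    valid: np.ndarray


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows: [-b·gx², -b·gy², -b·gz², -2b·gx·gy, -2b·gx·gz, -2b·gy·gz, 1].

    Solves for (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0).
    """
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    return np.column_stack(
        [
            -bvals * gx**2,
            -bvals * gy**2,
            -bvals * gz**2,
            -2 * bvals * gx * gy,
            -2 * bvals * gx * gz,
            -2 * bvals * gy * gz,
            np.ones_like(bvals),
        ]
    )


def fit_dti(
    dwi: np.ndarray,
    scheme,
    mask: np.ndarray,
    method: str = "wls",
    signal_floor_frac: float = 1e-6,
) -> TensorField:
    """Fit a diffusion tensor per in-mask voxel.

    Multiple b0 volumes are averaged into a single baseline before fitting.
    ``method='lls'`` is ordinary least squares on the log signal;
    ``'wls'`` adds a second pass reweighted by the squared predicted
    signal.  Non-positive signals are floored at
    ``signal_floor_frac × S0`` before the log (QC-flagged).

    Raises
    ------
    InsufficientSchemeError
        Fewer than 6 non-collinear diffusion directions, or no b0 volume.
    """
    if method not in ("lls", "wls"):
        raise ParameterError(f"unknown fit method {method!r}")
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    b0 = scheme.b0_mask
    if not b0.any():
        raise InsufficientSchemeError("scheme has no b0 volume")
    dirs = scheme.directions[~b0]
    bv = scheme.b_values[~b0]
    quad = _design_matrix(bv, dirs)[:, :6]
    if dirs.shape[0] < 6 or np.linalg.matrix_rank(quad) < 6:
        raise InsufficientSchemeError(
            "tensor fit needs >= 6 non-collinear diffusion-weighted directions"
        )

    s0 = dwi[..., b0].mean(axis=-1)
    signals = np.concatenate([s0[..., None], dwi[..., ~b0]], axis=-1)
    bvals = np.concatenate([[0.0], bv])
    bvecs = np.vstack([np.zeros(3), dirs])
    X = _design_matrix(bvals, bvecs)  # (m, 7)

    vox = signals[mask]  # (nvox, m)
    floor = signal_floor_frac * np.maximum(s0[mask], 1e-300)[:, None]
    clamped = vox < floor
    y = np.log(np.maximum(vox, floor))

    # first pass: one pseudo-inverse for all voxels
    beta = y @ np.linalg.pinv(X).T  # (nvox, 7)
    singular = ~np.all(np.isfinite(beta), axis=1)

    if method == "wls":
        w = np.exp(2.0 * (beta @ X.T))  # squared predicted signal
        # batched weighted normal equations
        XtW = X.T[None, :, :] * w[:, None, :]  # (nvox, 7, m)
        lhs = XtW @ X  # (nvox, 7, 7)
        rhs = np.einsum("vpm,vm->vp", XtW, y)
        ok = np.isfinite(lhs).all(axis=(1, 2)) & np.isfinite(rhs).all(axis=1)
        beta2 = np.full_like(beta, np.nan)
        if ok.any():
            try:
                beta2[ok] = np.linalg.solve(lhs[ok], rhs[ok][..., None])[..., 0]
            except np.linalg.LinAlgError:
                for i in np.flatnonzero(ok):
                    try:
                        beta2[i] = np.linalg.solve(lhs[i], rhs[i])
                    except np.linalg.LinAlgError:
                        pass
        # voxels where the weighted pass failed keep their first-pass fit
        good = np.all(np.isfinite(beta2), axis=1)
        beta[good] = beta2[good]

    data = np.zeros(mask.shape + (6,))
    # reorder (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) -> (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)
    order = [0, 3, 4, 1, 5, 2]
    data[mask] = beta[:, order]

    valid = mask.copy()
    vi = np.flatnonzero(mask.ravel())
    valid.ravel()[vi[singular]] = False

    field_ = TensorField(data, valid)
    qc = np.zeros(mask.shape, dtype=np.int32)
    qc.ravel()[vi[np.any(clamped, axis=1)]] |= QC_LOG_CLAMP
    qc.ravel()[vi[singular]] |= QC_SINGULAR_FIT
    field_.qc = qc
    return field_


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA from eigenvalues (last axis): sqrt(3/2)·‖λ − MD‖ / ‖λ‖."""
    lam = np.asarray(eigenvalues, dtype=float)
    md = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - md, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def compute_scalar_maps(tensors: TensorField) -> ScalarMaps:
    """Eigen-decompose the tensor field and derive FA/MD/AD/RD/color-FA.

    Eigenvalues are sorted descending; negative eigenvalues are clamped to
    zero for metric computation and QC-flagged.  The principal eigenvector
    sign is fixed to have non-negative dot with +x̂ (ties: +ŷ, then +ẑ).
    """
    valid = tensors.valid
    mats = tensors.as_matrices()[valid]
    evals, evecs = np.linalg.eigh(mats)  # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]  # columns are eigenvectors

    neg = np.any(evals < 0, axis=1)
    evals_c = np.clip(evals, 0.0, None)

    e1 = evecs[:, :, 0]
    sign = np.sign(e1[:, 0])
    tie = sign == 0
    sign[tie] = np.sign(e1[tie, 1])
    tie = sign == 0
    sign[tie] = np.sign(e1[tie, 2])
    sign[sign == 0] = 1.0
    e1 = e1 * sign[:, None]

    md_v = evals_c.mean(axis=1)
    ad_v = evals_c[:, 0]
    rd_v = evals_c[:, 1:].mean(axis=1)
    fa_v = fractional_anisotropy(evals_c)

    shape = valid.shape

    def _expand(values, fill=np.nan, extra=()):
        out = np.full(shape + extra, fill)
        out[valid] = values
        return out

    qc = np.zeros(shape, dtype=np.int32)
    if hasattr(tensors, "qc"):
        qc |= tensors.qc
    vi = np.flatnonzero(valid.ravel())
    qc.ravel()[vi[neg]] |= QC_NEGATIVE_EIGENVALUE

    fa = _expand(fa_v)
    return ScalarMaps(
        fa=fa,
        md=_expand(md_v),
        ad=_expand(ad_v),
        rd=_expand(rd_v),
        color_fa=_expand(np.abs(e1) * fa_v[:, None], fill=0.0, extra=(3,)),
        e1=_expand(e1, fill=0.0, extra=(3,)),
        eigenvalues=_expand(evals, extra=(3,)),
        qc=qc,
        valid=valid.copy(),
    )
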