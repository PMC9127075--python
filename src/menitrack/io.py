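"""Thin NIfTI I/O wrappers used across the pipeline."""

from __future__ import annotations

import numpy as np
import nibabel as nib


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_nifti(path):
    """Returns (data array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine
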