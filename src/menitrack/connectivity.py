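"""Region-to-region connection matrices from streamlines and a parcellation."""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ParameterError
from .parcellation import Parcellation


@dataclass
class ConnectionMatrix:
    """Symmetric non-negative connection-strength matrix over region labels."""

    matrix: np.ndarray  # (k, k)
    codes: list  # label codes in row/column order
    names: list  # human-readable region name per code
    mode: str  # endpoint | passthrough
    normalization: str  # raw | volume
    n_dropped: int = 0  # streamlines with unassignable endpoints

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.names, columns=self.names)


def _region_name(entry: dict) -> str:
    parts = [entry.get("part"), entry.get("zone")]
    return " / ".join(p for p in parts if p) or "region"


def _snap_label(labels: np.ndarray, pt_vox: np.ndarray, tol_vox: float = 1.0) -> int:
    """Label at a voxel coordinate, snapping to the nearest label within tol."""
    shape = np.asarray(labels.shape)
    idx = np.rint(pt_vox).astype(int)
    if np.all((idx >= 0) & (idx < shape)):
        lab = int(labels[tuple(idx)])
        if lab > 0:
            return lab
    best, best_d = 0, np.inf
    r = int(np.ceil(tol_vox))
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dz in range(-r, r + 1):
                j = idx + (dx, dy, dz)
                if np.any(j < 0) or np.any(j >= shape):
                    continue
                lab = int(labels[tuple(j)])
                if lab == 0:
                    continue
                d = np.linalg.norm(j - pt_vox)
                if d <= tol_vox and d < best_d:
                    best, best_d = lab, d
    return best


def connection_matrix(
    streamlines,
    parcellation: Parcellation,
    mode: str = "endpoint",
    normalization: str = "raw",
    affine: np.ndarray | None = None,
) -> ConnectionMatrix:
    """Count region-pair connections made by a streamline set.

    ``endpoint`` mode increments the (first endpoint, last endpoint) cell
    per streamline; ``passthrough`` increments every pair of distinct
    regions the streamline visits, once per pair (single-region streamlines
    hit the diagonal).  Endpoints outside any label snap to the nearest
    label within 1 voxel, otherwise the streamline is dropped and counted.
    ``volume`` normalization divides cell (i, j) by sqrt(Vi·Vj) with V in
    voxels.  The result is symmetric.
    """
    if mode not in ("endpoint", "passthrough"):
        raise ParameterError(f"unknown mode {mode!r}")
    if normalization not in ("raw", "volume"):
        raise ParameterError(f"unknown normalization {normalization!r}")
    codes = parcellation.codes
    if not codes or not parcellation.support.any():
        raise ParameterError("parcellation is empty")
    if affine is None:
        affine = getattr(streamlines, "affine", np.eye(4))
    inv = np.linalg.inv(affine)
    labels = parcellation.labels
    code_index = {c: i for i, c in enumerate(codes)}
    k = len(codes)
    mat = np.zeros((k, k))
    n_dropped = 0

    lines = streamlines.streamlines if hasattr(streamlines, "streamlines") else streamlines
    for line in lines:
        pts_vox = np.asarray(line) @ inv[:3, :3].T + inv[:3, 3]
        if mode == "endpoint":
            a = _snap_label(labels, pts_vox[0])
            b = _snap_label(labels, pts_vox[-1])
            if a == 0 or b == 0:
                n_dropped += 1
                continue
            i, j = code_index[a], code_index[b]
            if i == j:
                mat[i, i] += 1
            else:
                mat[i, j] += 1
                mat[j, i] += 1
        else:
            idx = np.rint(pts_vox).astype(int)
            shape = np.asarray(labels.shape)
            ok = np.all((idx >= 0) & (idx < shape), axis=1)
            visited = np.unique(labels[idx[ok, 0], idx[ok, 1], idx[ok, 2]])
            visited = [v for v in visited if v > 0]
            if not visited:
                n_dropped += 1
                continue
            if len(visited) == 1:
                i = code_index[int(visited[0])]
                mat[i, i] += 1
            else:
                for a, b in combinations(visited, 2):
                    i, j = code_index[int(a)], code_index[int(b)]
                    mat[i, j] += 1
                    mat[j, i] += 1

    if normalization == "volume":
        counts = parcellation.counts()
        v = np.array([max(counts[c], 1) for c in codes], dtype=float)
        mat = mat / np.sqrt(v[:, None] * v[None, :])

    names = [_region_name(parcellation.table[c]) for c in codes]
    return ConnectionMatrix(mat, codes, names, mode, normalization, n_dropped)


def write_matrix_table(cm: ConnectionMatrix, path) -> None:
    cm.to_frame().to_csv(path, sep="\t")


def read_matrix_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def render_heatmap(cm: ConnectionMatrix, image_path, table_path=None, sidecar_path=None):
    """Write the heatmap raster plus a matching delimited-text table.

    Rows/columns are ordered as given in the matrix, which for the combined
    parcellation is (anterior, body, posterior) × (W-W, R-W, R-R).  The
    color scale is linear from 0 to the matrix maximum.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = float(cm.matrix.max())
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    im = ax.imshow(cm.matrix, cmap="inferno", vmin=0.0, vmax=vmax if vmax > 0 else 1.0)
    ax.set_xticks(range(len(cm.names)), cm.names, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(range(len(cm.names)), cm.names, fontsize=8)
    fig.colorbar(im, ax=ax, label=f"connection strength ({cm.normalization})")
    ax.set_title(f"region connectivity ({cm.mode} mode)")
    fig.tight_layout()
    fig.savefig(image_path, dpi=120)
    plt.close(fig)

    if table_path is not None:
        write_matrix_table(cm, table_path)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "codes": [int(c) for c in cm.codes],
                    "names": cm.names,
                    "mode": cm.mode,
                    "normalization": cm.normalization,
                    "n_dropped": int(cm.n_dropped),
                },
                fh,
                indent=2,
            )
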