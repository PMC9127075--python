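"""End-to-end orchestration: simulate → fit → parcellate → track → connect → summarize.

A run is fully described by a :class:`RunConfig` (loadable from YAML); all
randomness derives from one global seed fanned out to per-stage substreams,
and the emitted manifest records parameters, seeds and artifact checksums
so identical configs reproduce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .acquisition import paper_protocol_scheme, read_gradient_table, write_gradient_table
from .connectivity import connection_matrix, render_heatmap
from .errors import ParameterError
from .io import load_nifti, save_nifti
from .parcellation import (
    Parcellation,
    combine_parcellations,
    fit_rotation_frame,
    radial_segmentation,
    rotational_segmentation,
)
from .phantom import (
    PhantomSpec,
    TensorField,
    ground_truth_zone_labels,
    make_crescent_mask,
    make_tensor_field,
    synthesize_dwi,
)
from .stats import voxelwise_zone_anova, zonal_summary
from .tensor_fit import compute_scalar_maps, fit_dti
from .tracking import TrackingParams, track_streamlines, write_streamlines

# defaults the source protocol leaves unreported; surfaced in the manifest
UNREPORTED_DEFAULTS = {
    "tracking.step_size": "0.5 x voxel size",
    "tracking.fa_threshold": 0.05,
    "tracking.min_length": 0.0,
    "tracking.max_length": 100.0,
    "tracking.integrator": "fixed-step midpoint (rk2)",
    "tensor_fit.method": "wls",
    "connectivity.mode": "endpoint",
    "connectivity.normalization": "raw",
    "direction_scheme.optimizer": "antipodal electrostatic repulsion",
}


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    Exactly one of ``phantom`` (synthetic input parameters) or ``inputs``
    (paths: dwi, bval, bvec, mask) must be supplied.
    """

    output_dir: str = "menitrack_run"
    seed: int = 0
    phantom: dict | None = None
    inputs: dict | None = None
    fit: dict = field(default_factory=lambda: {"method": "wls"})
    parcellation: dict = field(
        default_factory=lambda: {"step_deg": 0.5, "body_span_deg": 60.0, "n_zones": 3}
    )
    tracking: dict = field(default_factory=dict)
    connectivity: dict = field(
        default_factory=lambda: {"mode": "endpoint", "normalization": "raw"}
    )

    def __post_init__(self):
        if (self.phantom is None) == (self.inputs is None):
            raise ParameterError("supply exactly one of 'phantom' or 'inputs'")
        if self.inputs is not None:
            missing = {"dwi", "bval", "bvec", "mask"} - set(self.inputs)
            if missing:
                raise ParameterError(f"inputs missing keys: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and return the run manifest (also written to disk).

    Artifacts, in order: DWI + gradient table (synthetic runs), tensor
    field + scalar maps, 3-zone/3-part/9-region parcellations, streamlines,
    connection matrix + heatmap, zonal table + ANOVA, manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _save_vol(name, data, affine):
        p = out / name
        save_nifti(data, affine, p)
        artifacts[name] = str(p)

    # ---- stage 1: inputs (synthetic or loaded) -----------------------------
    if config.phantom is not None:
        spec = PhantomSpec(**{**config.phantom, "seed": config.seed})
        scheme = paper_protocol_scheme(seed=config.seed)
        mask = make_crescent_mask(spec)
        gt_zones = ground_truth_zone_labels(mask, spec)
        tensors_true = make_tensor_field(mask, spec, zone_labels=gt_zones)
        dwi = synthesize_dwi(tensors_true, scheme, spec)
        affine = spec.affine
        _save_vol("mask.nii", mask, affine)
        _save_vol("gt_zones.nii", gt_zones.labels, affine)
        _save_vol("dwi.nii", dwi.astype(np.float32), affine)
        write_gradient_table(scheme, out / "dwi.bval", out / "dwi.bvec")
        artifacts["dwi.bval"] = str(out / "dwi.bval")
        artifacts["dwi.bvec"] = str(out / "dwi.bvec")
    else:
        dwi, affine = load_nifti(config.inputs["dwi"])
        mask, _ = load_nifti(config.inputs["mask"])
        mask = mask > 0
        scheme = read_gradient_table(config.inputs["bval"], config.inputs["bvec"])

    # ---- stage 2: tensor fit + scalar maps ---------------------------------
    tensors = fit_dti(dwi, scheme, mask, method=config.fit.get("method", "wls"))
    tensors.affine = affine
    maps = compute_scalar_maps(tensors)
    for name, vol in (
        ("fa.nii", maps.fa),
        ("md.nii", maps.md),
        ("ad.nii", maps.ad),
        ("rd.nii", maps.rd),
        ("color_fa.nii", maps.color_fa),
    ):
        _save_vol(name, np.nan_to_num(vol, nan=0.0).astype(np.float32), affine)
    _save_vol("qc.nii", maps.qc.astype(np.int16), affine)

    # ---- stage 3: parcellation ---------------------------------------------
    pconf = config.parcellation
    frame = fit_rotation_frame(mask)
    zones = radial_segmentation(
        mask, frame, step=pconf.get("step_deg", 0.5), n_zones=pconf.get("n_zones", 3)
    )
    parts = rotational_segmentation(mask, frame, body_span=pconf.get("body_span_deg", 60.0))
    regions = combine_parcellations(zones, parts)
    for name, parc in (("zones", zones), ("parts", parts), ("regions", regions)):
        _save_vol(f"{name}.nii", parc.labels, affine)
        parc.write_table(out / f"{name}.json")
        artifacts[f"{name}.json"] = str(out / f"{name}.json")

    # ---- stage 4: tractography ---------------------------------------------
    tconf = dict(config.tracking)
    max_seeds = tconf.pop("max_seeds", None)
    params = TrackingParams(**{**tconf, "rng_seed": config.seed})
    sset = track_streamlines(tensors, maps, mask, params, affine=affine, max_seeds=max_seeds)
    write_streamlines(sset, out / "tracts.trk")
    artifacts["tracts.trk"] = str(out / "tracts.trk")

    # ---- stage 5: connectivity ---------------------------------------------
    cm = connection_matrix(
        sset,
        regions,
        mode=config.connectivity.get("mode", "endpoint"),
        normalization=config.connectivity.get("normalization", "raw"),
        affine=affine,
    )
    render_heatmap(
        cm,
        out / "connectivity.png",
        table_path=out / "connectivity.tsv",
        sidecar_path=out / "connectivity.json",
    )
    artifacts["connectivity.tsv"] = str(out / "connectivity.tsv")
    artifacts["connectivity.json"] = str(out / "connectivity.json")

    # ---- stage 6: zonal statistics -----------------------------------------
    table = zonal_summary(maps, zones)
    table.to_csv(out / "zonal_summary.tsv", sep="\t", index=False)
    artifacts["zonal_summary.tsv"] = str(out / "zonal_summary.tsv")
    anova = {}
    for metric in ("fa", "md", "ad", "rd"):
        f_stat, p = voxelwise_zone_anova(maps, zones, metric=metric)
        anova[metric] = {"F": f_stat, "p": p, "unit": "voxelwise (anti-conservative)"}
    with open(out / "anova.json", "w") as fh:
        json.dump(anova, fh, indent=2)
    artifacts["anova.json"] = str(out / "anova.json")

    # ---- manifest -----------------------------------------------------------
    # the heatmap raster is excluded from checksums (backend-dependent bytes)
    manifest = {
        "menitrack_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_streamlines": len(sset),
        "n_region_labels": int(len(np.unique(regions.labels[regions.labels > 0]))),
        "unreported_defaults": UNREPORTED_DEFAULTS,
        "checksums": {name: _sha256(p) for name, p in sorted(artifacts.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
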