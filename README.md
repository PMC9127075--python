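# menitrack

Analysis pipeline for diffusion MRI of crescent-shaped (meniscal) tissue:
automatic zonal/part parcellation of a C-shaped binary mask, voxelwise
diffusion-tensor quantification (FA/MD/AD/RD, color-FA), deterministic
streamline tractography with a 45° turning-angle stopping rule, and
region-to-region connectivity heatmaps.  A synthetic phantom module
generates crescent masks, zone-dependent fibrous tensor fields, and noisy
diffusion-weighted volumes so the whole chain is testable end to end
without scanner data.

## Modules

| module | purpose |
| --- | --- |
| `menitrack.acquisition` | gradient schemes: uniform half-sphere direction generation (antipodal electrostatic repulsion), Stejskal–Tanner b-value physics, FSL-dialect bval/bvec I/O |
| `menitrack.phantom` | crescent masks, circumferential/radial/mixed tensor fields, DWI forward simulation with Rician noise, ground-truth zone labels |
| `menitrack.tensor_fit` | LLS/WLS tensor estimation, eigen-decomposition, scalar maps with QC flags |
| `menitrack.parcellation` | rotation-frame fitting (PCA + debiased circle fit), radial 3-zone trisection (W-W/R-W/R-R), rotational 3-part split (anterior/body/posterior), 9-region combination |
| `menitrack.tracking` | bidirectional fixed-step principal-eigenvector tracking (.trk/.tck I/O) |
| `menitrack.connectivity` | endpoint/passthrough connection matrices, heatmap + table rendering |
| `menitrack.stats` | zonal volume/metric summaries, one-way ANOVA, percent change |
| `menitrack.pipeline` / `menitrack.cli` | reproducible end-to-end runs with a checksummed manifest |

## CLI

```bash
menitrack run-all --out run_dir --seed 1           # phantom -> heatmap, all artifacts
menitrack simulate --out sim --grid 64 --snr 20    # synthetic DWI + mask + bval/bvec
menitrack fit --dwi sim/dwi.nii --bval sim/dwi.bval --bvec sim/dwi.bvec \
              --mask sim/mask.nii --out maps
menitrack parcellate --mask sim/mask.nii --out parc --mode combined \
              --step-deg 0.5 --body-span-deg 60 --n-zones 3
menitrack track --tensors maps/tensors.nii --fa maps/fa.nii --mask sim/mask.nii \
              --out tracts.trk
menitrack connect --tracts tracts.trk --labels parc/regions.nii \
              --table parc/regions.json --out conn
menitrack summarize --labels parc/zones.nii --table parc/zones.json \
              --maps-dir maps --out zonal.tsv
```

`run-all` also accepts a YAML config (`--config run.yaml`) with keys
`phantom` *or* `inputs` (dwi/bval/bvec/mask paths), plus `fit`,
`parcellation`, `tracking`, `connectivity`, `seed`, `output_dir`.  The
emitted `manifest.json` records seeds, parameters, versions and SHA-256
checksums of every data artifact; identical configs reproduce identical
checksums.

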