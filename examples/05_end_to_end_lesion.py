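"""Full pipeline: can a subtle cortical diffusivity lesion be recovered?

Inserts a +0.15 um^2/ms focal lesion into the cortical ribbon, runs the
complete chain (acquisition simulation at SNR ~ 20, repetition averaging
with noise-floor correction, per-shell super-resolution, two-shell MDT),
and compares the lesion region against the mirrored contralateral cortex.
Also prints the CSF-stratified partial-volume bias table of the run.
"""

import shutil
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

import mdtmap as m
from mdtmap.pipeline import resample_volume

center, radius = (18.6, 0.0, 0.0), 7.0
cfg = m.PipelineConfig(
    phantom={"shape": (48, 48, 48), "spacing": 1.0},
    lesions=[m.LesionSpec("focal_hyperintense", center, radius, 0.15)],
    noise_sigma=0.05,
    seed=1,
)

out = Path(tempfile.mkdtemp()) / "run"
manifest = m.run_pipeline(cfg, out)
print("pipeline wrote", len(manifest["outputs"]), "files; config hash",
      manifest["config_hash"])

values, affine = m.read_nifti(out / "mdt.nii")
valid, _ = m.read_nifti(out / "mdt_valid.nii")
phantom = m.PhantomVolume.load(out / "phantom")
grid = m.Grid(values.shape, affine)
cortex = resample_volume(phantom.fractions["cortex"], phantom.grid, grid)
centers = grid.voxel_centers().reshape(*grid.shape, 3)
in_cortex = (cortex >= 0.5) & (valid > 0.5)
roi = (np.linalg.norm(centers - np.array(center), axis=-1) <= radius) & in_cortex
con = (np.linalg.norm(centers + np.array(center), axis=-1) <= radius) & in_cortex
print(f"lesion-ROI mean MDT      {values[roi].mean():.3f} um^2/ms")
print(f"contralateral mean MDT   {values[con].mean():.3f} um^2/ms")
print(f"contrast                 {values[roi].mean() - values[con].mean():+.3f} "
      f"(inserted +0.150)")

print("\nCSF-stratified bias (um^2/ms):")
print(pd.read_csv(out / "pv_bias_report.tsv", sep="\t").to_string(index=False))
shutil.rmtree(out.parent, ignore_errors=True)
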