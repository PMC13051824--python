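# mdtmap

CSF-suppressed tissue mean-diffusivity (**MDT**) mapping: a library and CLI
for two-shell high-b spherical-tensor-encoding diffusivity estimation, with
a rotated thick-slice acquisition simulator, model-based super-resolution
reconstruction, and digital brain phantoms for end-to-end validation.

## The problem

Conventional mean-diffusivity (MD/ADC) maps are computed from the b = 0
signal, so any voxel sharing volume with cerebrospinal fluid (CSF) mixes in
the fast free-water signal and its apparent diffusivity is biased high.
Cortical gray matter — a thin ribbon wedged between CSF and white matter —
is exactly where this partial-volume confound is worst, and where subtle
diffusivity changes (cortical malformations, low-grade tumors, ischemia)
matter clinically.

The MDT approach estimates diffusivity from the log-slope between two
*high* b-values under spherical b-tensor encoding:

```
MDT = [ln S(b1) − ln S(b2)] / (b2 − b1),    b1 = 1500, b2 = 2500 s/mm²
```

With free water at D ≈ 3.0 μm²/ms, the CSF signal at b = 2500 s/mm² is
exp(−7.5) ≈ 0.055% of its b = 0 level — below 1% — so both shells are
effectively CSF-free and the slope reflects tissue alone. Spherical
encoding makes each compartment's attenuation depend only on trace(D)/3,
removing orientation effects that would otherwise contaminate a
single-direction high-b measurement. The price is SNR: high b plus a long
echo time forces thick slices (5.2 mm), which are recovered to isotropic
1.53 mm resolution by acquiring the stack in six rotations about the
anterior–posterior axis and solving a regularized super-resolution inverse
problem. The resulting maps can be displayed with a tight window
(0.5–0.9 μm²/ms) in which cortex and white matter are near-isointense and
CSF is dark.

Because clinical raw data for this kind of protocol are not generally
available, the package includes a first-class synthetic-data path: digital
head phantoms with partial-volume boundaries and known tissue diffusivity,
a forward simulator of the rotated thick-slice multi-shell session
(including Rician noise per acquired volume), and a bias report that
quantifies exactly how much CSF contamination each estimator admits.

## What is in the box

| module                | contents |
|-----------------------|----------|
| `mdtmap.signal`       | multi-compartment Gaussian signal under spherical/linear b-tensor encoding, Rician noise, shell-table (`BTensorProtocol`) with JSON sidecar |
| `mdtmap.phantom`      | concentric head phantom (CSF rim + sulci, cortical ribbon, WM core, ventricles, deep nuclei) with supersampled partial-volume fractions, insertable lesions, CSF-excluded ground truth |
| `mdtmap.acquisition`  | sparse forward operator (rotate → slice-profile blur → decimate), session simulation, repetition averaging with optional Rician noise-floor correction |
| `mdtmap.srr`          | per-shell super-resolution by conjugate-gradient regularized least squares with exact adjoints |
| `mdtmap.estimate`     | MDT/ADC maps with signal-floor validity, cortical masking, display windowing, CSF-stratified bias report |
| `mdtmap.pipeline`/`cli` | end-to-end runs from a YAML/JSON config, NIfTI + manifest outputs, `mdtmap` console command |

## Worked example

`examples/02_partial_volume_bias.py` evaluates the closed-form bias of both
estimators for a tissue voxel (0.7 μm²/ms) progressively contaminated by
CSF:

```
CSF fraction    MDT bias    ADC bias  (um^2/ms, truth 0.7)
         0.0     +0.0000     +0.0000
         0.1     +0.0032     +0.0943
         0.2     +0.0071     +0.1984
         0.3     +0.0122     +0.3146
         0.4     +0.0188     +0.4461
         0.5     +0.0281     +0.5976
```

At 30% CSF the conventional b = 0–1000 ADC overestimates tissue
diffusivity by +0.315 μm²/ms (~45%) while the two-shell estimate is off by
only +0.012 μm²/ms (~1.7%).

`examples/05_end_to_end_lesion.py` runs the whole chain — 48³ phantom with
a +0.15 μm²/ms focal cortical lesion, 246 simulated volumes at SNR ≈ 20,
noise-floor-corrected averaging, super-resolution to 1.53 mm, two-shell
estimation — and prints:

```
lesion-ROI mean MDT      0.997 um^2/ms
contralateral mean MDT   0.824 um^2/ms
contrast                 +0.172 (inserted +0.150)
```

i.e. the inserted diffusivity change is recovered through the full
measurement chain. The other examples demonstrate CSF suppression
(`01`), phantom/acquisition anatomy (`03`), and solver diagnostics (`04`).

The same run is available from the shell:

```bash
mdtmap run-all --config examples/demo_config.yaml --seed 1 --out scratch/demo
mdtmap report scratch/demo
```

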