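# Methods

## Signal model

Each voxel is a mixture of Gaussian diffusion compartments with signal
fractions `f_i` (Σf_i ≤ 1; the remainder is zero-signal background). Under
spherical b-tensor encoding a compartment attenuates as
`exp(−b·MD·10⁻³)` with MD = trace(D)/3 in μm²/ms and b in s/mm²; under
linear encoding along unit vector g as `exp(−b·gᵀDg·10⁻³)`. The spherical
form is orientation-invariant by construction, which is what lets a
two-point high-b slope be read as a scalar tissue property. CSF is modeled
as free water with `FREE_WATER_DIFFUSIVITY = 3.0 μm²/ms` (the standard
body-temperature free-water value), giving exp(−7.5) ≈ 5.5×10⁻⁴ residual
signal at b = 2500 s/mm².

T2/TE weighting is folded into the compartment fractions: fractions are
signal fractions *at the protocol's fixed TE* (110 ms). No relaxometry,
exchange, kurtosis or non-Gaussian behavior is modeled.

Magnitude noise is Rician: `|s + n₁ + i·n₂|` with n₁, n₂ ~ N(0, σ), applied
per acquired repetition (as a scanner would), never after averaging.

## Phantom

The digital head is concentric: air background, a CSF rim with six sulcal
invaginations (Gaussian wedges of constant angular width whose arc length
is set at the head surface, so they narrow with depth), a cortical ribbon,
a white-matter core containing two ventricles, and optional deep nuclei.
Boundary voxels carry fractional occupancies from supersampled point
classification (3³ points per voxel by default), so partial-volume mixing —
the phenomenon under test — exists by construction rather than by
resampling accident. Default diffusivities: cortex 0.8, WM 0.7, CSF 3.0,
deep nuclei 0.7 μm²/ms.

Dimensions scale with the grid (head radius 0.92 of the half-FOV,
ventricles 0.18 of head radius) except the cortical ribbon (4 mm default)
and sulcal width (2 mm): a 48 mm phantom is a scaled-down head, and a
ribbon much thinner than the 5.2 mm slices would leave no voxels to read.
These are phantom-design choices, documented here because real cortex is
thinner (~2.5–3 mm) — conclusions about absolute cortical coverage do not
transfer to real anatomy.

Lesions are spheres that shift the per-class MD maps (focal: cortex;
tumor: cortex+WM; ischemia: negative shift) leaving fractions untouched:
they change diffusivity, not anatomy.

**Ground truth.** The target quantity is defined as the *CSF-excluded*
fraction-weighted mean diffusivity: `Σ f_c·MD_c / Σ f_c` over non-CSF
tissue classes, invalid where the tissue fraction is < 0.05. This is the
quantity a CSF-suppressed estimator should recover, and it is by definition
invariant to the CSF fraction at fixed tissue composition. This definition
is stated prominently because "tissue diffusivity in a mixed voxel" admits
alternatives (e.g. including CSF, or majority-class MD); everything the
bias report measures is relative to this definition.

## Acquisition forward model

One stack measurement is `y = D·B·R·x`: tri-linear resampling onto the
rotated stack frame, convolution along the slice axis with the slice
profile, decimation to the stack grid. The three factors are fused into a
single sparse matrix — rows are stack voxels, built from profile taps along
the slice normal, each tap tri-linearly interpolated in the source grid —
so the adjoint needed by the reconstruction is the exact sparse transpose
(adjoint identity holds to machine precision, and the operator is verified
against an independently coded dense construction on small instances).

Numerical choices: profile taps are spaced at the source grid's finest
spacing (boxcar: equal sub-interval midpoints, so matched unit geometry is
an exact identity; Gaussian: ±2.5σ support with FWHM = slice thickness),
weights normalized to unit DC gain. Stack grids cover the source FOV with
whole-slice padding so profile support never truncates at the edge, and
whole-voxel padding preserves center alignment. Samples outside the source
volume contribute zero.

The slice profile is not stated by thick-slice EPI protocols generally;
both Gaussian (default) and boxcar are supported and recorded in the
manifest, because the choice materially affects super-resolution
conditioning (boxcar inverts better). Rotation angles default to six
evenly spaced over [0°, 180°): 0, 30, …, 150 — even spacing maximizes
angular coverage when only the count is prescribed. EPI distortions,
GRAPPA/SMS, partial Fourier and motion are not simulated; the denoising
and distortion-correction stages exist as documented identity hooks so the
pipeline order matches a real processing chain.

## Repetition averaging and the noise floor

Averaging happens per (rotation, shell) before reconstruction. Plain
magnitude averaging retains the Rician bias E[M] > s, which at the b = 2500
shell (s ≈ 0.1–0.17 at σ = 0.05) is several percent and — because it is
larger for weaker signals — *compresses* diffusivity contrast: a closed-form
evaluation at σ = 0.05 shows a 0.15 μm²/ms cortical lesion contrast shrinks
to ≈ 0.08 if the floor is left in. The default averaging therefore uses the
second-moment identity E[M²] = s² + 2σ²:

```
ŝ = sqrt( max( mean(M²) − 2σ², 0 ) )
```

which is unbiased in s² and removes the floor (verified by simulation to
< 0.005 residual bias at SNR 2–3). It requires σ, taken from the stack
set's recorded noise level; with σ = 0 (or `method="mean"`) it reduces to
the arithmetic mean. Log-then-average is deliberately not offered: the
average must precede the log to keep the estimator's floor semantics.

## Super-resolution reconstruction

Each shell is reconstructed independently (keeping the diffusivity
estimation separable) by solving

```
x̂ = argmin_x Σ_r ‖A_r x − y_r‖² + λ‖Lx‖²
```

with conjugate gradients on the normal equations, matrix-free. This is a
standard model-based SRR formulation derived from first principles; it is
validated internally (dense-solve oracle ≤ 12³, adjoint identity, noiseless
self-consistency) rather than claimed to replicate any specific published
solver. L is the 3-D first difference by default (identity available for
algebraic tests). λ defaults to 10⁻² *relative to the data-term scale*
(multiplied by the mean diagonal of Σ AᵀA) so its strength is geometry-
independent; `lambda_mode="absolute"` bypasses the scaling. CG stops at
relative residual 10⁻⁶ or 300 iterations; non-convergence is reported in
diagnostics with the partial result flagged, not raised. Negative
intensities are not clamped in the solver (it stays linear); the signal
floor is applied downstream.

The default target grid is the axis-aligned intersection of the stack FOVs
at the finest in-plane spacing — for the reference geometry, isotropic
1.53 mm.

## Diffusivity estimation

`MDT = [ln S(b₁) − ln S(b₂)]/(b₂ − b₁)·10³` μm²/ms with natural logs
(b₁ = 1500, b₂ = 2500 s/mm² by default); the conventional ADC uses the
b = 0 signal. Signals at or below a configurable floor (10⁻⁶) mark the
voxel invalid rather than clamped — a rectified noise floor must not
masquerade as low diffusivity. Exactness: mono-exponential inputs are
inverted to ≤ 10⁻¹² relative error; any noiseless mixture estimate lies
within [min, max] compartment MD (mean-value bound).

Cortical masks are resampled to the map grid with nearest-neighbor
semantics (each mask voxel covers ±half a voxel); intensity volumes are
resampled tri-linearly. Display windowing maps [0.5, 0.9] μm²/ms to [0, 1]
with invalid voxels rendered dark — the tight window is usable precisely
because CSF is suppressed rather than bright.

## Validation scale and what it shows

Tests and the acceptance script run on 16³–48³ phantoms at 1 mm spacing
with the reference protocol (1/16/24 repetitions × 6 rotations = 246
volumes); these sizes were chosen as the smallest at which the cortical
ribbon, slice thickness and reconstruction grid keep their real proportions.
The three-seed end-to-end check recovers an inserted +0.15 μm²/ms cortical
lesion to 0.15 ± 0.05 at σ = 0.05 (SNR ≈ 20 at b = 0).

Known limitations, hence what passing tests do *not* show: no
susceptibility/eddy distortions, motion, fat or air-interface artifacts, no
gyrified anatomy, no T2*-driven darkening of iron-rich nuclei (a low-SNR
stand-in can be emulated by lowering the local fractions, but it is
speculative), no waveform-level encoding effects (Maxwell terms), and noise
is spatially white — real reconstructed EPI noise is neither white nor
stationary. The per-voxel MDT noise at this SNR is substantial
(RMSE ≈ 0.2 μm²/ms per 1.53 mm voxel); conclusions are about ROI means,
not single voxels. In noisy runs the log of a noisy low signal inflates
ROI-mean MDT slightly (concave-log bias, visible as a few-percent
overestimate at b = 2500 signal levels); this is a property of log-slope
estimation at low SNR, shared with the real method.
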