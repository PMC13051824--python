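# End-to-end demo: 48^3 phantom, reference protocol, focal cortical lesion.
phantom:
  shape: [48, 48, 48]
  spacing: 1.0
lesions:
  - kind: focal_hyperintense
    center_mm: [18.6, 0.0, 0.0]
    radius_mm: 7.0
    delta_md: 0.15
protocol:
  shells:
    - {b: 0,    shape: spherical, dir: null, reps: 1}
    - {b: 1500, shape: spherical, dir: null, reps: 16}
    - {b: 2500, shape: spherical, dir: null, reps: 24}
  te_ms: 110.0
  tr_ms: 2100.0
geometry:
  in_plane_mm: [1.53, 1.53]
  slice_thickness_mm: 5.2
  rotation_axis: AP
  rotation_angles_deg: [0, 30, 60, 90, 120, 150]
  slice_profile: gaussian
noise_sigma: 0.05
seed: 1
srr:
  regularizer: first_difference
  lam: 0.01
  lambda_mode: scaled
  tol: 1.0e-06
  max_iter: 300
estimator:
  b1: 1500.0
  b2: 2500.0
  floor: 1.0e-06
  window: [0.5, 0.9]
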