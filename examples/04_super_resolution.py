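"""Super-resolution reconstruction of isotropic shells from thick slices.

Reconstructs each shell of a noiseless simulated session onto the isotropic
grid implied by the in-plane spacing (1.53 mm for the reference geometry)
by conjugate-gradient regularized least squares, and reports solver
diagnostics plus the in-head agreement with a directly sampled reference.
"""

import numpy as np

import mdtmap as m
from mdtmap.pipeline import resample_volume

phantom = m.build_phantom((48, 48, 48), spacing=1.0)
session = m.simulate_session(
    phantom, m.default_protocol(repetitions=(1, 1, 1)), m.StackGeometry(), sigma=0.0
)
shells, grid, diags = m.reconstruct_all_shells(m.average_repetitions(session))

print("reconstruction grid:", grid.shape, "spacing", np.round(grid.spacing, 2), "mm")
head = resample_volume(phantom.total_fraction(), phantom.grid, grid) > 0.9
for i, (shell, d) in enumerate(zip(m.default_protocol().shells, diags)):
    ref = resample_volume(phantom.shell_signal(shell.b), phantom.grid, grid)
    err = np.abs(shells[i] - ref)[head].mean()
    print(f"  b={int(shell.b):4d}: {d.iterations:3d} CG iterations, "
          f"relative residual {d.relative_residual:.1e}, "
          f"mean in-head error {err:.4f}")
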