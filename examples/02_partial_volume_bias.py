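"""Partial-volume bias: two-shell MDT vs conventional ADC.

For a voxel mixing tissue (0.7 um^2/ms) with increasing amounts of CSF
(3.0 um^2/ms), compares the error of the high-b two-shell estimate against
the conventional b=0-1000 ADC. Closed form, no noise: this is the bias the
acquisition design removes, not an artifact of reconstruction.
"""

import numpy as np

import mdtmap as m

print(f"{'CSF fraction':>12}{'MDT bias':>12}{'ADC bias':>12}  (um^2/ms, truth 0.7)")
for f in np.arange(0.0, 0.51, 0.1):
    comps = [m.DiffusionCompartment(0.7, 1 - f)]
    if f > 0:
        comps.append(m.DiffusionCompartment(m.FREE_WATER_DIFFUSIVITY, f))
    mix = m.CompartmentMixture(tuple(comps))
    mdt = m.compute_mdt(m.mixture_signal(mix, 1500.0), m.mixture_signal(mix, 2500.0))
    adc = m.compute_adc(m.mixture_signal(mix, 0.0), m.mixture_signal(mix, 1000.0), 1000.0)
    print(f"{f:>12.1f}{mdt - 0.7:>+12.4f}{adc - 0.7:>+12.4f}")

print("\nAt 30% CSF the ADC overestimates tissue diffusivity by ~45%;")
print("the two-shell estimate stays within ~2% of the tissue truth.")
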