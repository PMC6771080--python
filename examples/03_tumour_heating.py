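"""Transient tumour heating for three ferrofluid concentrations.

Embeds a 2 mL tumour in a coarse phantom, applies the published tumour power
densities for phi_r in {0.35, 0.5, 1.0} (mobilised particles), integrates
the Pennes equation for 10 minutes and prints the tumour-centre temperatures.
"""

import numpy as np

from mfhplan import PhantomConfig, embed_tumour, generate_phantom
from mfhplan.bioheat import BioheatParams, mnp_source_map, simulate, steady_state

ph = generate_phantom(PhantomConfig(grid=48, spacing=3.0e-3), seed=1)
ph = embed_tumour(ph, centre=(0.072, 0.072, 0.045), volume=2.0e-6)
print(f"tumour: {ph.tumour_mask.sum()} voxels "
      f"({ph.tumour_mask.sum()*ph.spacing**3*1e6:.2f} mL)")

params = BioheatParams(dt=2.0)
T0 = steady_state(ph, params)
ci = tuple(np.round(np.argwhere(ph.tumour_mask).mean(axis=0)).astype(int))
print(f"baseline tumour centre: {T0[ci]:.2f} degC")

powers = {0.35: 84.2e3, 0.5: 121.0e3, 1.0: 243.0e3}  # W/m^3, mobilised
print("\nphi_r   P(kW/m^3)   T_centre(degC)   T_min(degC)  after 600 s")
for phi, p in powers.items():
    run = simulate(ph, T0, mnp_source_map(ph, p), params, duration=600.0)
    tum = run.final[ph.tumour_mask]
    print(f"{phi:5.2f}   {p/1e3:9.1f}   {run.final[ci]:14.2f}   {tum.min():11.2f}")
print("\nTemperature rises monotonically with concentration; the tumour rim")
print("stays cooler than the centre because it loses heat to perfused tissue.")
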