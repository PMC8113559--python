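"""Decompose the pulsatile velocity field into radial and axial shear rates.

Evaluates the analytic field of the reference condition (amplitude 1 mm/s,
mean flow 4 mm/s, 1 Hz) on the 100 x 100 grid and prints the ranges of the
two shear components and the axial-to-radial ratio in the 16-um center band.
"""

import numpy as np

import rouleaux as rx

flow = rx.FlowParams(A_f=1e-3, B_f=4e-3)
grid = rx.GridSpec()

snap = rx.shear_decompose(flow, grid, t=0.0)
print(f"axial shear gx range : {snap.gx.min():7.1f} .. {snap.gx.max():6.1f} 1/s")
print(f"radial shear gy range: {snap.gy.min():7.1f} .. {snap.gy.max():6.1f} 1/s")

ratios = [rx.center_band_ratio(flow, grid, t) for t in np.linspace(0, 1, 200, endpoint=False)]
print(f"center-band |gx|/|gy| ratio over one cycle: "
      f"min {min(ratios):.3f}, max {max(ratios):.3f}")

# The axial component (+-25 1/s here) is tiny next to the radial one
# (hundreds of 1/s at the walls), but near the tube axis the radial shear
# vanishes and the axial shear is what organizes rouleaux into parabolic
# patterns; the center-band ratio tracks that competition through the cycle.
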