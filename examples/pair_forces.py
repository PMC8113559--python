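"""The three forces of the model at hand-picked configurations.

Prints the Hertzian contact force for a 1-um overlap, the Morse depletion
force at characteristic gaps, and the Stokes drag on a stationary cell in
the mean flow — the numbers that set the scales of the dynamics.
"""

import math

import numpy as np

import rouleaux as rx
from rouleaux.mechanics import PairGeometry

mp = rx.MechParams()
ex = np.array([1.0, 0.0])

f_el = rx.elastic_force(mp, PairGeometry(d=2 * mp.R - 1e-6, n_ij=ex, R=mp.R))
print(f"elastic force, 1 um overlap      : {f_el[0]:.3e} N (repulsive)")

gap = mp.delta0 + math.log(2) / mp.B
f_ag = rx.aggregation_force(mp, PairGeometry(d=2 * mp.R + gap, n_ij=ex, R=mp.R))
print(f"depletion force at gap {gap*1e9:.1f} nm  : {f_ag[0]:.3e} N (attractive)")

f_dr = rx.drag_force(mp, u_local=[4e-3, 0.0], v_particle=[0.0, 0.0])
print(f"Stokes drag, stationary in 4 mm/s: {f_dr[0]:.3e} N")

print(f"\ndrag relaxation time m/(6 pi mu R): {mp.tau*1e6:.2f} us")
print(f"aggregation/drag force ratio      : {abs(f_ag[0]/f_dr[0]):.1e}")
print("-> with the literature depletion constant the cohesion is negligible;")
mp_cal = mp.calibrated()
f_cal = rx.aggregation_force(mp_cal, PairGeometry(d=2 * mp.R + gap, n_ij=ex, R=mp.R))
print(f"   the calibrated scale DA = {mp_cal.DA:.0e} J gives {f_cal[0]:.2e} N, "
      "strong enough for rouleaux to survive the shear flow.")
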