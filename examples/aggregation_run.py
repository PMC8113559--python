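"""One pulsatile aggregation run with per-decile quantification.

Simulates 533 cells for two 1 Hz cycles at the strongest reference
condition (amplitude 1.3 mm/s, mean flow 4 mm/s) with the calibrated
depletion strength, then reports the normalized aggregated-cell count in
each equal-area axial-shear decile at phase t/T = 0.9, the mean
aggregation size, and the center-band shear ratio.

Takes about a minute on one CPU (reduce n_cycles or N to go faster).
"""

import rouleaux as rx

cfg = rx.SimulationConfig(
    flow=rx.FlowParams(A_f=1.3e-3, B_f=4e-3),
    mech=rx.MechParams().calibrated(),
    n_cycles=2,
    seed=7,
)
traj = rx.run_simulation(cfg)

df = rx.decile_metrics(traj, source="gx", phase=0.9)
by_bin = df.groupby("roi_id")[["mean_gx", "normalized_count"]].mean()
print("axial-shear deciles at t/T = 0.9 (averaged over cycles):")
print(by_bin.round(3).to_string())
print(f"\npeak normalized count : {rx.peak_normalized_count(traj):.2f}")
print(f"mean aggregation size : {df['MAS_global'].iloc[-1]:.1f} cells/aggregate")
print(f"center-band gx/gy     : {df['center_ratio'].iloc[-1]:.3f}")

# A normalized count above 1 means the decile holds more aggregated cells
# than a uniform suspension would place there: the travelling sinusoid
# compresses cells near the axial-shear minimum, where depletion attraction
# locks them into rouleaux.
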