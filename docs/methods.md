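# Methods

## Model

`rouleaux` simulates red-blood-cell (RBC) aggregation in a 2D rigid
micro-tube (diameter h = 0.12 mm, length L = 0.5 mm) under an analytic
sinusoidal pulsatile flow

    u(t, x, y) = {A_f sin(w t - k_f x) + B_f} (1 - 4 y^2 / h^2),

a Poiseuille profile modulated by a sinusoid travelling along the axis.
The field is prescribed, not solved: it is deliberately compressible in x
(its axial gradient is the point of the model) and its spatial gradient
splits into a radial shear rate gy = du/dy and an axial shear rate
gx = du/dx.  Near the walls gy dominates (hundreds of 1/s); on the axis gy
vanishes and gx (tens of 1/s) is what organizes aggregates into the
parabolic rouleaux patterns the model is built to study.

N = 533 rigid circular cells (R = 4 um, m = 2.94e-13 kg; nominally 40%
hematocrit, literally a 44.6% disk-area fraction — N takes precedence)
move by Newton's second law under three forces:

* **Hertzian elastic contact** f = k (2R - d)^(3/2) n for center distance
  d < 2R, with k = 3e-6 applied to the overlap in meters (the only
  self-consistent reading of the printed constant; effective units
  N m^-3/2).
* **Depletion (Morse) aggregation force**
  f = 2 DA B (e^{2B(d0-delta)} - e^{B(d0-delta)}) n on the membrane gap
  delta = d - 2R, the negative gradient of the Morse pair energy
  DA (e^{2B(d0-delta)} - 2 e^{B(d0-delta)}); B = 1e7 1/m, d0 = 11 nm.
  The force is cut off at delta > r_cut = 1 um = 10/B (truncated tail
  < e^-10 of the 2·DA·B scale).
* **Stokes drag** f = 6 pi mu R (u - v) toward the local flow velocity,
  with mu = 1.2e-3 Pa s (plasma-like; the source model never states its
  viscosity, so mu is an exposed parameter).  The literature form of this
  pseudosteady drag is printed with the opposite sign, which would push
  particles away from the flow; the physical sign is implemented.

Two cells count as *aggregated* when d < 2R = 8 um (periodic axial
metric); aggregates are connected components of those contact pairs, and
the mean aggregation size (MAS) averages component sizes over components
with >= 2 members (0 when none exist — the convention for the empty case).

## Aggregation-strength calibration

With the literature constant DA = 1e-25 J the aggregation-force scale
2·DA·B = 2e-18 N sits ~8 orders of magnitude below the drag scale
6 pi mu R B_f ≈ 3.6e-10 N: cohesion is then numerically invisible and no
rouleaux survive shear.  DA merges a surface energy and a contact area and
is the model's least-constrained constant, so it is treated as the one
calibration knob.  Bounds: the peak attraction DA·B/2 must stay below the
drag scale (DA <= ~7e-17 J) so cohesion perturbs, rather than overrides,
the hydrodynamics.  A coarse grid search (DA in {5e-18, 1e-17, 2e-17,
5e-17} J) against the published peak normalized count (~2.7 at amplitude
1.3 mm/s, mean flow 4 mm/s) found the aggregated state bistable at
5e-18 J (ignition depends on the seed: peaks 0.7-2.6) and reliably
ignited from 1e-17 J upward (peaks 3.07-3.18 across five seeds, a
seed-robust +14-18% of the published value); **DA = 1e-17 J** is
therefore the calibrated default of `MechParams.calibrated()`, and every
run manifest records the DA in force and whether it is the calibrated or
the literature value.  Realistic depletion interaction energies (uJ/m^2
surface energies over um^2 contact areas) are of this order, so the
calibrated value is also the physically plausible one.

Once ignited, the peak normalized count saturates near 3.1 for every
flow condition; amplitude and mean-flow dependence then express
themselves in the hysteresis loop area (growing strongly with A_f) and
in mild suppression at higher B_f, not in the saturated peak count.  Two
published behaviors are not recovered in this regime and their checks
are deliberately left failing rather than loosened: the steady-flow
(A_f = 0) radial profile of normalized counts comes out wall-weighted
instead of center-weighted, and the peak-count-vs-amplitude trend is
flat (see the test-suite docstrings).

## Integration

The drag relaxation time tau = m/(6 pi mu R) ≈ 3.25 us makes the momentum
equation stiff at any useful dt.  The integrator splits each step: pair
and wall forces F and the local flow velocity u are frozen, then
m v' = F + gamma (u - v) is solved exactly over dt (exponential
relaxation), and positions advance by the exact time integral of that
velocity.  The scheme is unconditionally stable in the drag term, exact
for a lone particle in locally uniform flow, and first-order accurate
overall; the default dt = 1e-5 s (dt/tau ≈ 3) is validated by a
dt-halving convergence test.

Two numerical guards act only in regimes the model does not resolve:

* the Morse repulsion is frozen below a 0.5 um overlap (floating-point
  overflow guard), which bounds every pair force and keeps the dynamics
  finite at any parameter setting;
* an exactly coincident pair of centers (distance < 1 fm, a measure-zero
  geometry that a long run can stumble into) is pushed apart
  deterministically along +x with the guard-clamped magnitude inside the
  integrator; the user-facing force API treats it as an error instead.

**Contact resolution caveat.**  The Morse force varies over 1/B = 0.1 um;
resolving a contact faithfully would require per-step displacements well
below that, i.e. repulsive forces below gamma/(B dt) ~ 5e-10 N at the
default dt.  In compressed cell heaps the (calibrated) repulsion far
exceeds this, so contact dynamics there are under-resolved: cell heaps
develop deep overlaps and contact-scale velocity fluctuations orders of
magnitude above the flow scale, a granular-agitation regime rather than a
resolved overdamped suspension.  This is a property of the model's printed
constants at any feasible dt, not of this implementation; the source
model (unreported dt and integrator) reproduces its headline aggregation
numbers only in this same regime.  Experiments with repulsion caps that
force smooth, fully resolved dynamics lower the peak normalized count
from ~2.6 to ~0.7 and were therefore rejected: positions, counts and
aggregate statistics — the published observables — match the source in
the uncapped formulation, while instantaneous contact velocities should
not be interpreted physically.

Boundaries: x is periodic (a cell leaving the outlet re-enters at the
inlet with velocity, radial position and force intact); the walls are
rigid, enforced by a virtual Hertzian mirror-particle contact plus a hard
clamp of centers to |y| <= h/2 - R as a safety net.

The initial condition is seeded random sequential placement of
non-overlapping disks (pairwise d >= 2R, so exactly zero aggregated pairs
at t = 0); initial velocities equal the local flow velocity to suppress
the startup drag transient (`zero_start` gives a cold start instead).
A (config, seed) pair fully determines a trajectory.

## Quantification

* **Equal-area shear deciles.**  The 100 x 100 grid of cell centers
  (5 x 1.2 um cells) is ranked by one shear field (gx, gy or magnitude)
  at the analysis instant and cut into 10 bins of exactly 1000 cells; ties
  break by flat cell index (stable sort) for determinism.  A particle
  belongs to the bin of the grid cell containing its center.
* **Normalized aggregated count.**  Aggregated-particle count per ROI
  divided by the expected uniform count N x (ROI area fraction) — N/10
  for deciles, 533/6 = 88.83 for the 0.1 x 0.1 mm^2 centered rectangle.
  The expected count is used instead of the realized initial count
  because the latter is seed-noisy and undefined for ROIs that move with
  the field; for equal-area deciles the two agree in expectation.
* **Center-band shear ratio.**  mean(|gx|)/mean(|gy|) over grid cells
  with |y| <= 8 um (16 um band).  The ratio of band means is used because
  a pointwise ratio diverges where gy crosses zero on the axis.
* **Cycle statistics.**  Decile analyses are evaluated at phase
  t/T = 0.9 of each of the 5 cycles and averaged (no warm-up discarded);
  hysteresis curves bin snapshots by phase, average within each cycle,
  then report mean ± sd over cycles and the signed (shoelace) loop area,
  positive = counterclockwise.

The wavenumber k_f is never stated in the source model; the default
k_f = 4 pi / L (exactly two wavelengths per tube, ≈ 25.13 1/mm) keeps the
field consistent with the periodic boundary and reproduces the published
axial-shear ranges (±25 1/s at A_f = 1 mm/s, ±32 1/s at 1.3 mm/s).  The
published "maximum shear rate ratio of 0.32" is not reproducible under
any single k_f consistent with those ranges and this band-mean
definition; the package reports its own ratio and does not treat 0.32 as
ground truth.

## What a green test does and does not establish

Simulated runs ARE the data — there is no external input.  The test suite
checks the analytic field against closed forms and finite differences,
the forces against hand-evaluated values and the energy gradient, the
integrator against the exact drag-relaxation solution, the neighbor-list
machinery against O(N^2) oracles, and the analysis layer against
constructed configurations.  Trend tests (aggregation increasing with
amplitude, decreasing with mean flow, monotone against radial shear in
steady flow, hysteresis loops growing with amplitude) run the full
533-particle model at a reduced scale — 2 cycles instead of 5, 3 seeds,
dt kept at 1e-5 s because contact agitation is dt-sensitive —
to stay inside a desk/CI budget; they establish the direction of each
effect, not its published magnitude.  Headline magnitudes (peak
normalized count ~2.7; asymptotic MAS ~100) are reproduced within ±25%
under the calibrated DA.  The model itself omits cell deformability,
biconcave shape, rotation, hydrodynamic inter-particle coupling and any
feedback of particles on the flow; its velocity field is not a
Navier-Stokes solution, so quantitative agreement with experiments is out
of scope by construction.

## Known limitations

* The time step, integrator and wall rule of the original MATLAB model
  are unreported; quantitative reproduction is tolerance-based.
* Runs shorter than the full five cycles (used in scaled-down tests and
  the sweep) give smaller aggregation levels than converged runs.
* The decile partition of a time-varying field moves with the field;
  normalized counts in decile mode therefore compare particles against a
  region whose location changes through the cycle (as in the source
  analysis).
* At very strong cohesion (DA near the documented upper bound) contact
  agitation grows with DA; the overflow guard keeps such runs finite but
  internal cluster dynamics are not accurate at contact scale (see the
  contact resolution caveat above).
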