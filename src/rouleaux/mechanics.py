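"""Pairwise and hydrodynamic forces of the RBC particle model.

Three forces act on each cell:

* a Hertzian elastic contact force ``k * (2R - d)^(3/2)`` when two cells
  overlap (d < 2R),
* a depletion aggregation force derived from a Morse pair potential
  ``Phi(delta) = DA * (exp(2B(d0-delta)) - 2 exp(B(d0-delta)))`` with
  ``delta = d - 2R`` the membrane gap, attractive for ``delta > d0``,
* pseudosteady Stokes drag ``6 pi mu R (u - v)`` toward the local flow
  velocity.

``DA`` is the merged product of the depletion surface energy and the
cell-cell apposition area, so the aggregation-force scale is ``2*DA*B``.
With the literature constants used as defaults this scale is many orders of
magnitude below the drag scale and cohesion is negligible; a calibrated
value ``DA_CALIBRATED`` is provided for runs that are meant to exhibit
rouleaux formation (see docs/methods.md for the calibration bounds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MechParams",
    "PairGeometry",
    "DA_CALIBRATED",
    "elastic_force",
    "morse_potential",
    "aggregation_force",
    "drag_force",
    "accumulate_forces",
]

#: Depletion energy scale (J) calibrated so that cohesion competes with the
#: viscous shear forces of the default flow and rouleaux actually form;
#: the literature default 1e-25 J yields forces ~8 orders below drag.
#: Bounds for legitimate calibration: the peak attraction DA*B/2 must not
#: exceed the drag scale 6*pi*mu*R*B_f (~3.6e-10 N), i.e. DA <= ~7e-17 J.
#: 1e-17 J is the smallest grid value at which rouleaux formation ignites
#: reliably across seeds (5e-18 J is bistable), and matches physically
#: plausible depletion energies (uJ/m^2 surface energy over um^2
#: apposition area).
DA_CALIBRATED = 1e-17

#: Overlap depth (m) below which the Morse repulsion is frozen to avoid
#: floating-point overflow; contact repulsion there is the elastic term's job.
_OVERLAP_GUARD = -0.5e-6


@dataclass(frozen=True)
class MechParams:
    """Mechanical constants of an RBC-mimicking particle (SI units).

    ``k`` multiplies the 3/2-power of the overlap expressed in meters
    (effective units N * m^-3/2).  ``r_cut`` truncates the Morse pair force
    on the surface gap; with the default ``r_cut = 10/B`` the truncated tail
    is below ``exp(-10)`` of the force scale ``2*DA*B``.
    """

    R: float = 4e-6
    m: float = 2.94e-13
    k: float = 3e-6
    DA: float = 1e-25
    B: float = 1e7
    delta0: float = 11e-9
    mu: float = 1.2e-3
    r_cut: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("R", "m", "k", "DA", "B", "delta0", "mu", "r_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MechParams.{name} must be strictly positive")
        if self.r_cut * self.B < math.log(1e4):
            raise ValueError("r_cut too short: Morse truncation error above 1e-4")

    @property
    def gamma(self) -> float:
        """Stokes drag coefficient 6*pi*mu*R (kg/s)."""
        return 6.0 * math.pi * self.mu * self.R

    @property
    def tau(self) -> float:
        """Drag relaxation time m / (6*pi*mu*R) (s); ~3.25 us at defaults."""
        return self.m / self.gamma

    def calibrated(self, DA: float = DA_CALIBRATED) -> "MechParams":
        """Copy with the aggregation energy scale set to a calibrated value."""
        return replace(self, DA=DA)


@dataclass(frozen=True)
class PairGeometry:
    """Geometry of one particle pair: center distance, membrane gap, direction.

    ``n_ij`` is the unit vector from particle j toward particle i, so a
    positive force magnitude along ``n_ij`` pushes the pair apart.
    """

    d: float
    n_ij: np.ndarray
    R: float

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("center distance must be non-negative")
        if self.d == 0.0:
            raise ValueError("coincident particle centers: pair direction undefined")
        n = np.asarray(self.n_ij, dtype=float)
        if not math.isclose(float(np.hypot(*n)), 1.0, rel_tol=1e-9):
            raise ValueError("n_ij must be a unit vector")

    @property
    def delta(self) -> float:
        """Membrane (surface) gap d - 2R; negative when the cells overlap."""
        return self.d - 2.0 * self.R

    @classmethod
    def between(cls, pos_i, pos_j, R: float) -> "PairGeometry":
        rij = np.asarray(pos_i, dtype=float) - np.asarray(pos_j, dtype=float)
        d = float(np.hypot(*rij))
        if d == 0.0:
            raise ValueError("coincident particle centers: pair direction undefined")
        return cls(d=d, n_ij=rij / d, R=R)


def elastic_force(mp: MechParams, pg: PairGeometry) -> np.ndarray:
    """Hertzian contact force on particle i: k*(2R-d)^(3/2) n_ij for d < 2R."""
    overlap = 2.0 * mp.R - pg.d
    if overlap <= 0.0:
        return np.zeros(2)
    return mp.k * overlap**1.5 * np.asarray(pg.n_ij, dtype=float)


def morse_shape(mp: MechParams, delta) -> np.ndarray | float:
    """Dimensionless Morse well exp(2B(d0-delta)) - 2 exp(B(d0-delta)).

    Minimum value -1 at ``delta = delta0``; energy is ``DA * shape``.
    """
    a = mp.B * (mp.delta0 - np.asarray(delta, dtype=float))
    return np.exp(2.0 * a) - 2.0 * np.exp(a)


def morse_potential(mp: MechParams, delta) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Return ``(shape, energy)`` of the Morse pair potential at gap ``delta``.

    ``shape`` is the dimensionless bracket; ``energy = DA * shape`` in joules,
    with global minimum ``-DA`` at ``delta = delta0``.
    """
    s = morse_shape(mp, delta)
    return s, mp.DA * s


def _aggregation_magnitude(mp: MechParams, delta: float) -> float:
    # positive = repulsive (along n_ij); clamp deep overlaps (guard) to keep
    # the exponentials finite -- the elastic term dominates there anyway
    delta = max(delta, _OVERLAP_GUARD)
    a = mp.B * (mp.delta0 - delta)
    return 2.0 * mp.DA * mp.B * (math.exp(2.0 * a) - math.exp(a))


def aggregation_force(mp: MechParams, pg: PairGeometry) -> np.ndarray:
    """Depletion (Morse) force on particle i; zero beyond the gap cutoff.

    Repulsive for gaps below ``delta0``, attractive between ``delta0`` and
    ``r_cut``; equals ``-d(DA*shape)/d(delta)`` along ``n_ij``.
    """
    if pg.delta > mp.r_cut:
        return np.zeros(2)
    return _aggregation_magnitude(mp, pg.delta) * np.asarray(pg.n_ij, dtype=float)


def drag_force(mp: MechParams, u_local, v_particle) -> np.ndarray:
    """Stokes drag 6*pi*mu*R*(u - v): drives the particle toward the flow."""
    u = np.asarray(u_local, dtype=float)
    v = np.asarray(v_particle, dtype=float)
    return mp.gamma * (u - v)


def pair_force(mp: MechParams, pg: PairGeometry) -> np.ndarray:
    """Total interparticle force (elastic + aggregation) on particle i."""
    return elastic_force(mp, pg) + aggregation_force(mp, pg)


def accumulate_forces(mp: MechParams, fp, state, t: float) -> np.ndarray:
    """Per-particle total force: pairwise elastic + aggregation plus drag.

    Uses the cell-list neighbor search of the simulation kernels; every pair
    with surface gap below ``r_cut`` is found, with the axial coordinate
    treated periodically.  Pairwise contributions obey Newton's third law
    exactly by construction (each pair is evaluated once and applied with
    opposite signs).

    Parameters
    ----------
    mp, fp : MechParams, FlowParams
    state : ParticleState
        Positions and velocities of all particles.
    t : float
        Time at which the flow field is evaluated.
    """
    from . import _kernels
    from .flow import velocity_at

    pos = np.ascontiguousarray(state.pos, dtype=np.float64)
    f = _kernels.pairwise_forces(
        pos, fp.L, fp.h, mp.R, mp.k, mp.DA, mp.B, mp.delta0, mp.r_cut
    )
    if not np.all(np.isfinite(f)):
        bad = np.flatnonzero(~np.isfinite(f).all(axis=1))
        raise ValueError(
            f"coincident particle centers involving particle(s) {bad[:5].tolist()}: "
            "pair direction undefined"
        )
    u = np.zeros_like(pos)
    u[:, 0] = velocity_at(fp, t, pos[:, 0], pos[:, 1])
    f += mp.gamma * (u - state.vel)
    return f
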