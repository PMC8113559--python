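"""Analytic sinusoidal pulsatile velocity field and its shear-rate decomposition.

The model flow is a Poiseuille profile modulated by a sinusoid travelling
along the tube axis,

    u(t, x, y) = {A_f sin(w t - k_f x) + B_f} (1 - 4 y^2 / h^2),

with purely axial velocity.  Its gradient splits into a radial shear rate
``gy = du/dy`` (the familiar Poiseuille component) and an axial shear rate
``gx = du/dx`` contributed by the travelling wave.  Everything here is
closed-form; the grid machinery only samples the analytic expressions at
cell centers.

All quantities are SI (m, s, rad).  Unit-bearing configuration files are
converted on load by :mod:`rouleaux.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FlowParams",
    "GridSpec",
    "ShearFieldSnapshot",
    "velocity_at",
    "radial_shear_at",
    "axial_shear_at",
    "shear_decompose",
    "center_band_ratio",
    "field_table",
]


@dataclass(frozen=True)
class FlowParams:
    """Parameters of the analytic pulsatile field.

    Attributes
    ----------
    A_f : float
        Velocity amplitude of the travelling sinusoid (m/s).
    B_f : float
        Mean flow velocity (m/s).
    f : float
        Pulse frequency (Hz); 1 Hz corresponds to 60 beats per minute.
    k_f : float or None
        Wavenumber (1/m).  ``None`` selects the default of exactly two
        wavelengths per tube length, ``4*pi/L``, which keeps the field
        consistent with the periodic axial boundary.
    h : float
        Tube diameter (m).
    L : float
        Tube length (m).
    """

    A_f: float = 1e-3
    B_f: float = 4e-3
    f: float = 1.0
    h: float = 0.12e-3
    L: float = 0.5e-3
    k_f: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.k_f is None:
            object.__setattr__(self, "k_f", 4.0 * math.pi / self.L)
        if self.h <= 0 or self.L <= 0:
            raise ValueError("tube dimensions must be positive")
        if self.f <= 0:
            raise ValueError("pulse frequency must be positive")
        if self.B_f <= 0:
            raise ValueError("mean flow velocity must be positive")
        if self.A_f < 0:
            raise ValueError("velocity amplitude must be non-negative")
        if self.k_f < 0:
            raise ValueError("wavenumber must be non-negative")

    @property
    def omega(self) -> float:
        """Angular frequency 2*pi*f (rad/s)."""
        return 2.0 * math.pi * self.f

    @property
    def T(self) -> float:
        """Pulsatile period 1/f (s)."""
        return 1.0 / self.f


@dataclass(frozen=True)
class GridSpec:
    """Uniform collocated grid over the tube cross-section.

    Cell centers live at ``x in [0, L)``, ``y in (-h/2, +h/2)``; with the
    default 100 x 100 grid on the 0.5 x 0.12 mm tube each cell is
    5 um x 1.2 um, smaller than one cell radius.
    """

    nx: int = 100
    ny: int = 100

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")

    def centers(self, p: FlowParams) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates ``(xc[nx], yc[ny])`` in meters."""
        dx = p.L / self.nx
        dy = p.h / self.ny
        xc = (np.arange(self.nx) + 0.5) * dx
        yc = (np.arange(self.ny) + 0.5) * dy - p.h / 2.0
        return xc, yc

    def mesh(self, p: FlowParams) -> tuple[np.ndarray, np.ndarray]:
        """Dense ``(ny, nx)`` meshes of cell-center coordinates."""
        xc, yc = self.centers(p)
        return np.meshgrid(xc, yc)

    def cell_of(self, p: FlowParams, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Flat grid-cell index (row-major ``iy*nx + ix``) containing each point."""
        ix = np.floor(np.asarray(x) / (p.L / self.nx)).astype(np.int64)
        iy = np.floor((np.asarray(y) + p.h / 2.0) / (p.h / self.ny)).astype(np.int64)
        ix = np.clip(ix, 0, self.nx - 1)
        iy = np.clip(iy, 0, self.ny - 1)
        return iy * self.nx + ix


@dataclass(frozen=True)
class ShearFieldSnapshot:
    """The analytic field sampled on the grid at one instant.

    ``u`` is the axial velocity, ``gx``/``gy`` the axial/radial shear rates,
    ``gmag`` their Pythagorean magnitude and ``phi`` the direction angle of
    the gradient vector ``(gx, gy)`` in (-pi, pi].  All arrays are
    ``(ny, nx)``, row-major in ``y``.
    """

    t: float
    u: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gmag: np.ndarray
    phi: np.ndarray


def _check_y(p: FlowParams, y) -> None:
    if np.any(np.abs(np.asarray(y)) > p.h / 2.0 * (1.0 + 1e-12)):
        raise ValueError("radial coordinate outside the tube: |y| > h/2")


def _envelope(p: FlowParams, y):
    return 1.0 - 4.0 * np.square(y) / p.h**2


def _pulse(p: FlowParams, t, x):
    return p.A_f * np.sin(p.omega * t - p.k_f * np.asarray(x)) + p.B_f


def velocity_at(p: FlowParams, t, x, y):
    """Axial velocity u(t, x, y) in m/s.  Zero at the walls (no slip)."""
    _check_y(p, y)
    return _pulse(p, t, x) * _envelope(p, y)


def radial_shear_at(p: FlowParams, t, x, y):
    """Radial shear rate gy = du/dy (1/s); antisymmetric in y."""
    _check_y(p, y)
    return -_pulse(p, t, x) * (8.0 * np.asarray(y) / p.h**2)


def axial_shear_at(p: FlowParams, t, x, y):
    """Axial shear rate gx = du/dx (1/s); vanishes at the walls."""
    _check_y(p, y)
    return (-p.A_f * p.k_f * np.cos(p.omega * t - p.k_f * np.asarray(x))) * _envelope(p, y)


def shear_decompose(p: FlowParams, g: GridSpec, t: float) -> ShearFieldSnapshot:
    """Evaluate velocity and both shear components on the grid at time ``t``."""
    X, Y = g.mesh(p)
    u = velocity_at(p, t, X, Y)
    gx = axial_shear_at(p, t, X, Y)
    gy = radial_shear_at(p, t, X, Y)
    gmag = np.hypot(gx, gy)
    phi = np.arctan2(gy, gx)
    return ShearFieldSnapshot(t=t, u=u, gx=gx, gy=gy, gmag=gmag, phi=phi)


def center_band_ratio(
    p: FlowParams, g: GridSpec, t: float, band_width: float = 16e-6
) -> float:
    """Axial-to-radial shear-rate ratio in a band around the tube axis.

    Defined as ``mean(|gx|) / mean(|gy|)`` over grid cells whose centers lie
    within ``|y| <= band_width/2`` (default band 16 um).  The ratio of band
    means is used because a pointwise ratio diverges on the centerline where
    gy crosses zero.
    """
    if not 0.0 < band_width < p.h:
        raise ValueError("band_width must lie in (0, h)")
    _, yc = g.centers(p)
    sel = np.abs(yc) <= band_width / 2.0
    if not np.any(sel):
        raise ValueError("center band contains no grid cells")
    snap = shear_decompose(p, g, t)
    return float(np.mean(np.abs(snap.gx[sel, :])) / np.mean(np.abs(snap.gy[sel, :])))


def field_table(p: FlowParams, g: GridSpec, t: float):
    """Long-format field export: one row per grid cell, SI units.

    Returns a :class:`pandas.DataFrame` with columns
    ``(t, x_center, y_center, u, gx, gy, gmag, phi)``.
    """
    import pandas as pd

    snap = shear_decompose(p, g, t)
    X, Y = g.mesh(p)
    return pd.DataFrame(
        {
            "t": np.full(X.size, t),
            "x_center": X.ravel(),
            "y_center": Y.ravel(),
            "u": snap.u.ravel(),
            "gx": snap.gx.ravel(),
            "gy": snap.gy.ravel(),
            "gmag": snap.gmag.ravel(),
            "phi": snap.phi.ravel(),
        }
    )
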