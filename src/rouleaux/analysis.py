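"""Aggregation detection and quantification.

Two RBCs count as aggregated when their center distance is below the cell
diameter 2R = 8 um (computed with the periodic axial metric).  Aggregates
are the connected components of the resulting contact graph; the mean
aggregation size (MAS) averages the component sizes over components with
at least two members.

Local aggregation is quantified in regions of interest (ROIs): either the
10 equal-area rank-deciles of a shear-rate field on the grid, or a fixed
rectangle.  Counts of aggregated particles per ROI are normalized by the
expected uniform-distribution count (N x ROI-area fraction), so values
above 1 flag locally elevated hematocrit due to rouleaux formation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import _kernels
from .engine import ParticleState, Trajectory
from .flow import FlowParams, GridSpec, ShearFieldSnapshot, center_band_ratio, shear_decompose

__all__ = [
    "ROIPartition",
    "AggregationMetrics",
    "HysteresisCurve",
    "detect_aggregated",
    "aggregate_components",
    "mean_aggregation_size",
    "decile_partition",
    "rectangle_roi",
    "normalized_count",
    "roi_mean_shear",
    "hysteresis",
    "snapshot_metrics",
    "decile_metrics",
    "peak_normalized_count",
    "aggregation_timeseries",
]


@dataclass(frozen=True)
class ROIPartition:
    """Assignment of grid cells to ROIs.

    ``mode='decile'``: ``bin_index`` maps each flat grid-cell index to one of
    ``n_bins`` equal-area rank bins of ``source`` (bin 0 = lowest values).
    ``mode='rectangle'``: ``rect = (x0, x1, y0, y1)`` in meters.
    """

    mode: str
    n_bins: int = 10
    source: str | None = None
    bin_index: np.ndarray | None = None
    rect: tuple[float, float, float, float] | None = None


@dataclass(frozen=True)
class AggregationMetrics:
    """Per-snapshot aggregation summary."""

    t: float
    aggregated: np.ndarray          # (N,) bool
    component_sizes: np.ndarray     # sizes of components with >= 2 members
    mas: float
    normalized_counts: np.ndarray   # per ROI bin
    roi_mean_shear: np.ndarray      # per ROI bin, 1/s
    center_ratio: float


@dataclass(frozen=True)
class HysteresisCurve:
    """Cycle-averaged closed curve of (x, y) quantities vs. pulsatile phase."""

    phase: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    area: float  # signed loop area; positive = counterclockwise


def detect_aggregated(
    state: ParticleState | np.ndarray, R: float, L: float, h: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flag particles with a neighbor closer than 2R (periodic in x).

    Returns ``(flags, pair_i, pair_j)``; each aggregated pair appears once.
    """
    pos = state.pos if isinstance(state, ParticleState) else np.asarray(state)
    i, j = _kernels.close_pairs(pos, L, h, 2.0 * R)
    flags = np.zeros(pos.shape[0], dtype=bool)
    flags[i] = True
    flags[j] = True
    return flags, i, j


def aggregate_components(
    pair_i: np.ndarray, pair_j: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of the contact graph.

    Returns ``(labels, sizes)`` where ``sizes`` lists only components with
    at least two members (singletons are not aggregates).
    """
    if len(pair_i) == 0:
        return np.arange(n), np.empty(0, dtype=np.int64)
    data = np.ones(len(pair_i), dtype=np.int8)
    adj = coo_matrix((data, (pair_i, pair_j)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    counts = np.bincount(labels)
    return labels, counts[counts >= 2]


def mean_aggregation_size(component_sizes: Sequence[int] | np.ndarray) -> float:
    """Mean cells per aggregate over components of size >= 2; 0 if none."""
    sizes = np.asarray(component_sizes)
    sizes = sizes[sizes >= 2]
    return float(sizes.mean()) if sizes.size else 0.0


def decile_partition(
    snapshot: ShearFieldSnapshot, source: str = "gx", n_bins: int = 10
) -> ROIPartition:
    """Split the grid into equal-area rank bins of one shear field.

    Cells are ranked by the ``source`` field value (ties broken by flat cell
    index via a stable sort) and cut into ``n_bins`` bins of exactly
    ``nx*ny/n_bins`` cells each.
    """
    if source not in ("gx", "gy", "gmag"):
        raise ValueError("source must be one of 'gx', 'gy', 'gmag'")
    values = getattr(snapshot, source).ravel()
    ncells = values.size
    if ncells % n_bins:
        raise ValueError(f"{ncells} grid cells not divisible into {n_bins} equal bins")
    order = np.argsort(values, kind="stable")
    bin_index = np.empty(ncells, dtype=np.int64)
    bin_index[order] = np.arange(ncells) // (ncells // n_bins)
    return ROIPartition(mode="decile", n_bins=n_bins, source=source, bin_index=bin_index)


def rectangle_roi(
    fp: FlowParams,
    width: float = 0.1e-3,
    height: float = 0.1e-3,
    center: tuple[float, float] | None = None,
) -> ROIPartition:
    """Rectangular ROI (default 0.1 x 0.1 mm^2 centered on the tube axis)."""
    if center is None:
        center = (fp.L / 2.0, 0.0)
    x0, x1 = center[0] - width / 2.0, center[0] + width / 2.0
    y0, y1 = center[1] - height / 2.0, center[1] + height / 2.0
    if x0 < 0 or x1 > fp.L or y0 < -fp.h / 2.0 or y1 > fp.h / 2.0:
        raise ValueError("rectangle ROI extends outside the tube")
    return ROIPartition(mode="rectangle", n_bins=1, rect=(x0, x1, y0, y1))


def _particle_bins(
    pos: np.ndarray, partition: ROIPartition, fp: FlowParams, grid: GridSpec
) -> np.ndarray:
    """ROI bin of each particle (-1 = outside, rectangle mode only)."""
    if partition.mode == "decile":
        cells = grid.cell_of(fp, pos[:, 0], pos[:, 1])
        return partition.bin_index[cells]
    x0, x1, y0, y1 = partition.rect
    inside = (pos[:, 0] >= x0) & (pos[:, 0] < x1) & (pos[:, 1] >= y0) & (pos[:, 1] < y1)
    return np.where(inside, 0, -1)


def _baselines(partition: ROIPartition, fp: FlowParams, n_particles: int) -> np.ndarray:
    if partition.mode == "decile":
        return np.full(partition.n_bins, n_particles / partition.n_bins)
    x0, x1, y0, y1 = partition.rect
    frac = (x1 - x0) * (y1 - y0) / (fp.L * fp.h)
    return np.array([n_particles * frac])


def normalized_count(
    state: ParticleState | np.ndarray,
    partition: ROIPartition,
    flags: np.ndarray,
    fp: FlowParams,
    grid: GridSpec,
) -> np.ndarray:
    """Aggregated-particle count per ROI over the expected uniform count.

    The baseline is ``N x (ROI area / tube area)`` — N/10 for the equal-area
    deciles — so a value above 1 marks locally elevated hematocrit.
    """
    pos = state.pos if isinstance(state, ParticleState) else np.asarray(state)
    bins = _particle_bins(pos, partition, fp, grid)
    agg_bins = bins[flags & (bins >= 0)]
    counts = np.bincount(agg_bins, minlength=partition.n_bins).astype(float)
    return counts / _baselines(partition, fp, pos.shape[0])


def roi_mean_shear(
    snapshot: ShearFieldSnapshot, partition: ROIPartition, fp: FlowParams, grid: GridSpec,
    field: str = "gmag",
) -> np.ndarray:
    """Mean of a shear field (default magnitude) over each ROI's grid cells."""
    values = getattr(snapshot, field).ravel()
    if partition.mode == "decile":
        sums = np.bincount(partition.bin_index, weights=values, minlength=partition.n_bins)
        return sums / (values.size / partition.n_bins)
    x0, x1, y0, y1 = partition.rect
    X, Y = grid.mesh(fp)
    sel = (X.ravel() >= x0) & (X.ravel() < x1) & (Y.ravel() >= y0) & (Y.ravel() < y1)
    if not np.any(sel):
        raise ValueError("rectangle ROI contains no grid cells")
    return np.array([values[sel].mean()])


def hysteresis(
    times: np.ndarray,
    x_vals: np.ndarray,
    y_vals: np.ndarray,
    f: float,
    n_cycles: int = 5,
    n_phase: int = 20,
) -> HysteresisCurve:
    """Cycle-averaged hysteresis loop of two per-snapshot quantities.

    Samples are binned by pulsatile phase t/T mod 1; within each cycle the
    samples of a phase bin are averaged, then the mean and standard
    deviation over the ``n_cycles`` cycles are reported per bin.  The
    signed loop area of the mean curve (shoelace formula, positive =
    counterclockwise) quantifies the lag between the two quantities.
    """
    times = np.asarray(times, dtype=float)
    covered = times.max() * f
    # the last snapshot may fall one sampling interval short of the cycle end
    if covered + 1.0 / n_phase + 1e-9 < n_cycles:
        raise ValueError(
            f"trajectory covers {covered:.3g} cycles, fewer than the {n_cycles} configured"
        )
    tf = times * f
    cycle = np.minimum(np.floor(tf + 1e-9).astype(int), n_cycles - 1)
    phase_bin = np.floor((tf % 1.0) * n_phase).astype(int) % n_phase
    per_cycle = np.full((n_cycles, n_phase, 2), np.nan)
    for c in range(n_cycles):
        for b in range(n_phase):
            sel = (cycle == c) & (phase_bin == b)
            if np.any(sel):
                per_cycle[c, b, 0] = np.mean(np.asarray(x_vals)[sel])
                per_cycle[c, b, 1] = np.mean(np.asarray(y_vals)[sel])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(per_cycle, axis=0)
        sd = np.nanstd(per_cycle, axis=0, ddof=0)
    keep = ~np.isnan(mean[:, 0])
    phase = (np.arange(n_phase)[keep] + 0.5) / n_phase
    xm, ym = mean[keep, 0], mean[keep, 1]
    area = 0.5 * float(np.sum(xm * np.roll(ym, -1) - np.roll(xm, -1) * ym))
    return HysteresisCurve(
        phase=phase, x_mean=xm, x_sd=sd[keep, 0], y_mean=ym, y_sd=sd[keep, 1], area=area
    )


def snapshot_metrics(
    pos: np.ndarray,
    t: float,
    fp: FlowParams,
    grid: GridSpec,
    mech_R: float,
    partition: ROIPartition | None = None,
    source: str = "gx",
    band_width: float = 16e-6,
) -> AggregationMetrics:
    """All aggregation metrics of one snapshot (partition built at ``t`` if absent)."""
    snap = shear_decompose(fp, grid, t)
    if partition is None:
        partition = decile_partition(snap, source=source)
    flags, pi, pj = detect_aggregated(pos, mech_R, fp.L, fp.h)
    _, sizes = aggregate_components(pi, pj, pos.shape[0])
    return AggregationMetrics(
        t=t,
        aggregated=flags,
        component_sizes=sizes,
        mas=mean_aggregation_size(sizes),
        normalized_counts=normalized_count(pos, partition, flags, fp, grid),
        roi_mean_shear=roi_mean_shear(snap, partition, fp, grid),
        center_ratio=center_band_ratio(fp, grid, t, band_width),
    )


def _phase_snapshot_indices(traj: Trajectory, phase: float) -> list[int]:
    """Index of the recorded snapshot nearest ``phase`` within each cycle."""
    cfg = traj.config
    idx = []
    for c in range(cfg.n_cycles):
        target = (c + phase) / cfg.flow.f
        k = int(np.argmin(np.abs(traj.times - target)))
        idx.append(k)
    return idx


def decile_metrics(
    traj: Trajectory, source: str = "gx", phase: float = 0.9
) -> pd.DataFrame:
    """Per-cycle, per-decile aggregation table at one pulsatile phase.

    For each simulated cycle the recorded snapshot nearest phase t/T is
    analyzed against the decile partition of the chosen shear field at that
    instant.  Columns: cycle, roi_id, mean shear components, count,
    normalized_count, MAS_global, center_ratio.
    """
    cfg = traj.config
    fp, grid = cfg.flow, cfg.grid
    rows = []
    for c, k in enumerate(_phase_snapshot_indices(traj, phase)):
        t = traj.times[k]
        snap = shear_decompose(fp, grid, t)
        part = decile_partition(snap, source=source)
        m = snapshot_metrics(traj.pos[k], t, fp, grid, cfg.mech.R, partition=part)
        mean_gx = roi_mean_shear(snap, part, fp, grid, field="gx")
        mean_gy = roi_mean_shear(snap, part, fp, grid, field="gy")
        for b in range(part.n_bins):
            rows.append(
                {
                    "cycle": c,
                    "t": t,
                    "phase": phase,
                    "roi_id": b,
                    "roi_source": source,
                    "mean_gx": mean_gx[b],
                    "mean_gy": mean_gy[b],
                    "mean_gmag": m.roi_mean_shear[b],
                    "normalized_count": m.normalized_counts[b],
                    "MAS_global": m.mas,
                    "center_ratio": m.center_ratio,
                }
            )
    return pd.DataFrame(rows)


def peak_normalized_count(
    traj: Trajectory, source: str = "gx", phase: float = 0.9
) -> float:
    """Max over decile ROIs of the cycle-averaged normalized aggregated count."""
    df = decile_metrics(traj, source=source, phase=phase)
    return float(df.groupby("roi_id")["normalized_count"].mean().max())


def aggregation_timeseries(traj: Trajectory) -> pd.DataFrame:
    """Global aggregation level per recorded snapshot.

    Columns: t, phase, n_aggregated, n_components, MAS.
    """
    cfg = traj.config
    rows = []
    for k in range(traj.n_snapshots):
        flags, pi, pj = detect_aggregated(traj.pos[k], cfg.mech.R, cfg.flow.L, cfg.flow.h)
        _, sizes = aggregate_components(pi, pj, cfg.N)
        rows.append(
            {
                "t": traj.times[k],
                "phase": traj.times[k] * cfg.flow.f,
                "n_aggregated": int(flags.sum()),
                "n_components": len(sizes),
                "MAS": mean_aggregation_size(sizes),
            }
        )
    return pd.DataFrame(rows)
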