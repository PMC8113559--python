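"""Configuration files, trajectory persistence, run orchestration, exports.

Configuration is a flat YAML mapping with unit-bearing keys (velocities in
mm/s, lengths in um unless noted); everything is optional and defaults to
the reference condition (A_f = 1 mm/s, B_f = 4 mm/s, f = 1 Hz, N = 533 in
the 0.12 x 0.5 mm tube).  Documented keys:

=================  =============================================  =========
key                meaning                                        unit
=================  =============================================  =========
A_f                velocity amplitude                             mm/s
B_f                mean flow velocity                             mm/s
f                  pulse frequency                                Hz
k_f                wavenumber (default 4*pi/L)                    1/m
h                  tube diameter                                  um
L                  tube length                                    um
R                  RBC radius                                     um
m                  RBC mass                                       kg
k                  elastic contact prefactor                      N m^-3/2
DA                 depletion energy scale                         J
B                  Morse scaling factor                           1/m
delta0             Morse reference gap                            nm
mu                 medium viscosity                               Pa s
r_cut              pair-force gap cutoff                          um
nx, ny             grid cells per axis                            --
N                  particle count                                 --
hematocrit_label   nominal hematocrit                             --
dt                 time step                                      s
n_cycles           pulsatile cycles                               --
seed               RNG seed                                       --
record_stride      steps between recorded snapshots               --
zero_start         start particles at rest instead of the flow    bool
=================  =============================================  =========

Trajectories are stored in a single HDF5 container (/times, /pos, /vel plus
the config echoed as JSON); metrics, hysteresis curves and sweep summaries
are exported as CSV.  Every run writes a JSON manifest recording the
resolved configuration, seed, code version, outputs and wall time.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, analysis
from .engine import SimulationConfig, Trajectory, run_simulation
from .flow import FlowParams, GridSpec, field_table, shear_decompose
from .mechanics import MechParams

__all__ = [
    "load_config",
    "dump_config",
    "save_trajectory",
    "load_trajectory",
    "RunManifest",
    "run_and_save",
    "analyze_trajectory",
    "export_field",
    "run_sweep",
]

logger = logging.getLogger(__name__)

_FLOW_KEYS = {"A_f": 1e-3, "B_f": 1e-3, "f": 1.0, "k_f": 1.0, "h": 1e-6, "L": 1e-6}
_MECH_KEYS = {
    "R": 1e-6, "m": 1.0, "k": 1.0, "DA": 1.0, "B": 1.0,
    "delta0": 1e-9, "mu": 1.0, "r_cut": 1e-6,
}
_GRID_KEYS = {"nx", "ny"}
_RUN_KEYS = {
    "N", "hematocrit_label", "dt", "n_cycles", "seed", "record_stride", "zero_start",
}


def load_config(path: str | Path | None = None, **overrides) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from a YAML file.

    Omitted keys take the reference defaults; unknown keys are rejected.
    Keyword overrides (same keys and units as the file) win over the file.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must be a flat mapping")
        raw.update(loaded)
    raw.update(overrides)

    known = set(_FLOW_KEYS) | set(_MECH_KEYS) | _GRID_KEYS | _RUN_KEYS
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")

    flow_kwargs = {k: raw[k] * s for k, s in _FLOW_KEYS.items() if k in raw}
    mech_kwargs = {k: raw[k] * s for k, s in _MECH_KEYS.items() if k in raw}
    grid_kwargs = {k: int(raw[k]) for k in _GRID_KEYS if k in raw}
    run_kwargs = {k: raw[k] for k in _RUN_KEYS if k in raw}
    return SimulationConfig(
        flow=FlowParams(**flow_kwargs),
        mech=MechParams(**mech_kwargs),
        grid=GridSpec(**grid_kwargs),
        **run_kwargs,
    )


def dump_config(cfg: SimulationConfig, path: str | Path | None = None) -> dict:
    """Inverse of :func:`load_config`: the unit-bearing flat mapping."""
    out = {
        "A_f": cfg.flow.A_f / 1e-3,
        "B_f": cfg.flow.B_f / 1e-3,
        "f": cfg.flow.f,
        "k_f": cfg.flow.k_f,
        "h": cfg.flow.h / 1e-6,
        "L": cfg.flow.L / 1e-6,
        "R": cfg.mech.R / 1e-6,
        "m": cfg.mech.m,
        "k": cfg.mech.k,
        "DA": cfg.mech.DA,
        "B": cfg.mech.B,
        "delta0": cfg.mech.delta0 / 1e-9,
        "mu": cfg.mech.mu,
        "r_cut": cfg.mech.r_cut / 1e-6,
        "nx": cfg.grid.nx,
        "ny": cfg.grid.ny,
        "N": cfg.N,
        "hematocrit_label": cfg.hematocrit_label,
        "dt": cfg.dt,
        "n_cycles": cfg.n_cycles,
        "seed": cfg.seed,
        "record_stride": cfg.record_stride,
        "zero_start": cfg.zero_start,
    }
    if path is not None:
        Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
    return out


def save_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write the trajectory to one hierarchical HDF5 container."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["config_json"] = json.dumps(dump_config(traj.config))
        fh.attrs["version"] = __version__
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("pos", data=traj.pos, compression="gzip", compression_opts=4)
        fh.create_dataset("vel", data=traj.vel, compression="gzip", compression_opts=4)
    return path


def load_trajectory(path: str | Path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as fh:
        cfg = load_config(**json.loads(fh.attrs["config_json"]))
        return Trajectory(
            config=cfg,
            times=fh["times"][...],
            pos=fh["pos"][...],
            vel=fh["vel"][...],
        )


@dataclass
class RunManifest:
    """Provenance record of one run: config, seed, outputs, timing, sanity."""

    config: dict
    seed: int
    version: str
    outputs: list[str]
    wall_time_s: float
    max_speed_m_s: float
    DA: float
    DA_calibrated: bool

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


def run_and_save(cfg: SimulationConfig, outdir: str | Path) -> tuple[Trajectory, RunManifest]:
    """Run the simulation and persist trajectory + manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    traj = run_simulation(cfg)
    wall = time.perf_counter() - t0
    traj_path = save_trajectory(traj, outdir / "trajectory.h5")
    manifest = RunManifest(
        config=dump_config(cfg),
        seed=cfg.seed,
        version=__version__,
        outputs=[str(traj_path)],
        wall_time_s=wall,
        max_speed_m_s=float(np.max(np.abs(traj.vel))),
        DA=cfg.mech.DA,
        DA_calibrated=cfg.mech.DA != MechParams().DA,
    )
    manifest.write(outdir / "manifest.json")
    logger.info("run complete in %.1f s -> %s", wall, traj_path)
    return traj, manifest


def export_field(cfg: SimulationConfig, t: float, path: str | Path) -> Path:
    """CSV export of the analytic field on the grid at time ``t``."""
    path = Path(path)
    field_table(cfg.flow, cfg.grid, t).to_csv(path, index=False)
    return path


def analyze_trajectory(
    traj: Trajectory,
    outdir: str | Path,
    rois: tuple[str, ...] = ("decile-gx", "decile-gy", "decile-gmag", "rectangle"),
    n_phase: int = 20,
) -> dict[str, Path]:
    """Export aggregation metrics and hysteresis CSVs for the requested ROIs.

    ``metrics.csv`` has one row per (snapshot, ROI); ``hysteresis.csv`` one
    row per phase bin and ROI mode, pairing ROI mean shear magnitude (x)
    with the ROI normalized aggregated count (y).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = traj.config
    fp, grid = cfg.flow, cfg.grid

    metric_rows = []
    hyst_frames = []
    for roi in rois:
        mode = roi.split("-")[0]
        source = roi.split("-")[1] if "-" in roi else None
        series_x = np.empty(traj.n_snapshots)
        series_y = np.empty(traj.n_snapshots)
        for s in range(traj.n_snapshots):
            t = traj.times[s]
            snap = shear_decompose(fp, grid, t)
            if mode == "decile":
                part = analysis.decile_partition(snap, source=source)
            elif mode == "rectangle":
                part = analysis.rectangle_roi(fp)
            else:
                raise ValueError(f"unknown ROI mode {roi!r}")
            flags, pi, pj = analysis.detect_aggregated(traj.pos[s], cfg.mech.R, fp.L, fp.h)
            _, sizes = analysis.aggregate_components(pi, pj, cfg.N)
            mas = analysis.mean_aggregation_size(sizes)
            ncounts = analysis.normalized_count(traj.pos[s], part, flags, fp, grid)
            gmean = analysis.roi_mean_shear(snap, part, fp, grid)
            gx_mean = analysis.roi_mean_shear(snap, part, fp, grid, field="gx")
            gy_mean = analysis.roi_mean_shear(snap, part, fp, grid, field="gy")
            ratio = analysis.center_band_ratio(fp, grid, t)
            baselines = analysis._baselines(part, fp, cfg.N)
            for b in range(part.n_bins):
                metric_rows.append(
                    {
                        "t": t,
                        "phase": t * fp.f,
                        "roi_id": b,
                        "roi_source": roi,
                        "mean_gx": gx_mean[b],
                        "mean_gy": gy_mean[b],
                        "mean_gmag": gmean[b],
                        "count": ncounts[b] * baselines[b],
                        "normalized_count": ncounts[b],
                        "MAS_global": mas,
                        "center_ratio": ratio,
                    }
                )
            # hysteresis pair: ROI mean shear vs normalized count (peak bin
            # for deciles, the single bin for the rectangle)
            b = int(np.argmax(ncounts))
            series_x[s] = gmean[b]
            series_y[s] = ncounts[b]
        curve = analysis.hysteresis(
            traj.times, series_x, series_y, fp.f, n_cycles=cfg.n_cycles, n_phase=n_phase
        )
        hyst_frames.append(
            pd.DataFrame(
                {
                    "roi": roi,
                    "phase": curve.phase,
                    "x_mean": curve.x_mean,
                    "x_sd": curve.x_sd,
                    "y_mean": curve.y_mean,
                    "y_sd": curve.y_sd,
                    "loop_area": curve.area,
                }
            )
        )

    metrics_path = outdir / "metrics.csv"
    pd.DataFrame(metric_rows).to_csv(metrics_path, index=False)
    hyst_path = outdir / "hysteresis.csv"
    pd.concat(hyst_frames, ignore_index=True).to_csv(hyst_path, index=False)
    return {"metrics": metrics_path, "hysteresis": hyst_path}


def run_sweep(
    conditions: list[tuple[float, float, int]],
    base: SimulationConfig | None = None,
    phase: float = 0.9,
    source: str = "gx",
) -> pd.DataFrame:
    """Run one simulation per (A_f, B_f, seed) condition and summarize.

    ``A_f``/``B_f`` in m/s.  Each row reports the peak normalized
    aggregated count over decile ROIs (cycle-averaged at ``phase``), the
    center-band shear ratio and global MAS at the peak-aggregation
    snapshot, and the hysteresis loop area of (mean shear, normalized
    count) in the peak ROI.  A failed condition is recorded with an error
    message and the sweep continues.
    """
    if base is None:
        base = SimulationConfig()
    rows = []
    for A_f, B_f, seed in conditions:
        row = {"A_f": A_f, "B_f": B_f, "seed": seed}
        try:
            cfg = replace(base, flow=replace(base.flow, A_f=A_f, B_f=B_f), seed=seed)
            traj = run_simulation(cfg)
            row.update(summarize_run(traj, phase=phase, source=source))
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - sweep must survive bad points
            logger.warning("sweep condition (%g, %g, %d) failed: %s", A_f, B_f, seed, exc)
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) and (df["error"] != "").all():
        raise RuntimeError("all sweep conditions failed")
    return df


def summarize_run(traj: Trajectory, phase: float = 0.9, source: str = "gx") -> dict:
    """Headline numbers of one run (used per sweep condition)."""
    cfg = traj.config
    peak = analysis.peak_normalized_count(traj, source=source, phase=phase)
    ts = analysis.aggregation_timeseries(traj)
    k = int(ts["n_aggregated"].idxmax())
    ratio = analysis.center_band_ratio(cfg.flow, cfg.grid, float(ts["t"][k]))
    mas_max = float(ts["MAS"].max())
    # hysteresis of (ROI mean shear, normalized count) in the rectangle ROI
    rect = analysis.rectangle_roi(cfg.flow)
    xs = np.empty(traj.n_snapshots)
    ys = np.empty(traj.n_snapshots)
    for s in range(traj.n_snapshots):
        snap = shear_decompose(cfg.flow, cfg.grid, traj.times[s])
        flags, _, _ = analysis.detect_aggregated(traj.pos[s], cfg.mech.R, cfg.flow.L, cfg.flow.h)
        xs[s] = analysis.roi_mean_shear(snap, rect, cfg.flow, cfg.grid)[0]
        ys[s] = analysis.normalized_count(traj.pos[s], rect, flags, cfg.flow, cfg.grid)[0]
    curve = analysis.hysteresis(traj.times, xs, ys, cfg.flow.f, n_cycles=cfg.n_cycles)
    return {
        "peak_normalized_count": peak,
        "center_ratio_at_peak": ratio,
        "MAS_at_peak": float(ts["MAS"][k]),
        "MAS_max": mas_max,
        "n_aggregated_peak": int(ts["n_aggregated"][k]),
        "loop_area": curve.area,
    }
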