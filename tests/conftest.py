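"""Shared fixtures: default parameter sets and small, fast simulation configs."""

from dataclasses import replace

import numpy as np
import pytest

import rouleaux as rx


@pytest.fixture(scope="session")
def flow():
    """Reference flow: A_f = 1 mm/s, B_f = 4 mm/s, f = 1 Hz, default tube."""
    return rx.FlowParams()


@pytest.fixture(scope="session")
def mech():
    return rx.MechParams()


@pytest.fixture(scope="session")
def grid():
    return rx.GridSpec()


@pytest.fixture(scope="session")
def small_cfg():
    """Cheap run config: 60 particles, coarse dt, one cycle."""
    return rx.SimulationConfig(
        N=60, dt=1e-3, n_cycles=1, record_stride=10, seed=42
    )


@pytest.fixture(scope="session")
def small_traj(small_cfg):
    return rx.run_simulation(small_cfg)


def brute_force_pairs(pos, L, thresh):
    """O(N^2) oracle: all pairs with periodic-x center distance < thresh."""
    n = pos.shape[0]
    out = []
    for i in range(n):
        for j in range(i):
            dx = pos[i, 0] - pos[j, 0]
            dx -= L * np.round(dx / L)
            dy = pos[i, 1] - pos[j, 1]
            if dx * dx + dy * dy < thresh * thresh:
                out.append((i, j))
    return out


def brute_force_pair_forces(pos, L, mp):
    """O(N^2) numpy oracle for the summed elastic + Morse pair forces."""
    n = pos.shape[0]
    f = np.zeros((n, 2))
    for i in range(n):
        for j in range(i):
            dx = pos[i, 0] - pos[j, 0]
            dx -= L * np.round(dx / L)
            dy = pos[i, 1] - pos[j, 1]
            d = np.hypot(dx, dy)
            delta = d - 2 * mp.R
            if delta > mp.r_cut:
                continue
            mag = 0.0
            if delta < 0:
                mag += mp.k * (-delta) ** 1.5
            dd = max(delta, -0.5e-6)
            a = mp.B * (mp.delta0 - dd)
            mag += 2 * mp.DA * mp.B * (np.exp(2 * a) - np.exp(a))
            fx, fy = mag * dx / d, mag * dy / d
            f[i] += (fx, fy)
            f[j] -= (fx, fy)
    return f
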