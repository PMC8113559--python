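"""Aggregation metrics: detection, components, ROIs, hysteresis."""

import numpy as np
import pandas as pd
import pytest

import rouleaux as rx
from rouleaux import analysis

from conftest import brute_force_pairs

R = 4e-6
L = 0.5e-3
H = 0.12e-3


def state_from(pos):
    pos = np.asarray(pos, dtype=float)
    z = np.zeros_like(pos)
    return rx.ParticleState(t=0.0, pos=pos, vel=z, acc=z)


class TestDetect:
    def test_threshold_is_strict_8_microns(self):
        near = state_from([[1e-4, 0], [1e-4 + 7.9e-6, 0]])
        far = state_from([[1e-4, 0], [1e-4 + 8.1e-6, 0]])
        assert rx.detect_aggregated(near, R, L, H)[0].all()
        assert not rx.detect_aggregated(far, R, L, H)[0].any()

    def test_wrap_aware_distance(self):
        st = state_from([[0.1e-6, 0], [L - 0.1e-6, 0]])
        flags, i, j = rx.detect_aggregated(st, R, L, H)
        assert flags.all()
        assert len(i) == 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        pos = np.column_stack(
            [rng.uniform(0, L, 90), rng.uniform(-H / 2 + R, H / 2 - R, 90)]
        )
        _, i, j = rx.detect_aggregated(state_from(pos), R, L, H)
        got = {(int(a), int(b)) for a, b in zip(i, j)}
        want = set(brute_force_pairs(pos, L, 2 * R))
        assert got == want


class TestComponents:
    def test_chain_is_one_component(self):
        labels, sizes = rx.aggregate_components(
            np.array([1, 2]), np.array([0, 1]), 5
        )
        assert sorted(sizes.tolist()) == [3]
        assert labels[0] == labels[1] == labels[2]

    def test_no_pairs_no_aggregates(self):
        _, sizes = rx.aggregate_components(np.array([], int), np.array([], int), 7)
        assert len(sizes) == 0

    def test_partition_property(self):
        # sizes of >=2 components sum to the number of flagged particles
        rng = np.random.default_rng(1)
        pos = np.column_stack(
            [rng.uniform(0, L, 120), rng.uniform(-H / 2 + R, H / 2 - R, 120)]
        )
        flags, i, j = rx.detect_aggregated(state_from(pos), R, L, H)
        _, sizes = rx.aggregate_components(i, j, 120)
        assert sizes.sum() == flags.sum()


class TestMAS:
    @pytest.mark.parametrize(
        "sizes, expected",
        [([3], 3.0), ([2, 4], 3.0), ([], 0.0), ([1, 1, 1], 0.0), ([2, 2, 5], 3.0)],
    )
    def test_hand_built_sets(self, sizes, expected):
        assert rx.mean_aggregation_size(sizes) == expected

    def test_merging_two_components_does_not_decrease_mas(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            sizes = rng.integers(2, 30, size=rng.integers(2, 8)).tolist()
            merged = sizes[:-2] + [sizes[-1] + sizes[-2]]
            assert rx.mean_aggregation_size(merged) >= rx.mean_aggregation_size(sizes)


class TestDecilePartition:
    def test_equal_area_bins(self, flow, grid):
        snap = rx.shear_decompose(flow, grid, 0.0)
        for source in ("gx", "gy", "gmag"):
            part = rx.decile_partition(snap, source=source)
            counts = np.bincount(part.bin_index, minlength=10)
            assert np.all(counts == 1000)

    def test_constant_field_tie_break(self, flow, grid):
        snap = rx.shear_decompose(flow, grid, 0.0)
        const = rx.ShearFieldSnapshot(
            t=0.0, u=snap.u, gx=np.ones_like(snap.gx), gy=snap.gy,
            gmag=snap.gmag, phi=snap.phi,
        )
        part = rx.decile_partition(const, source="gx")
        # stable sort on a constant field: bins are consecutive index blocks
        np.testing.assert_array_equal(part.bin_index, np.arange(10000) // 1000)

    def test_monotone_field_gives_bands(self, grid):
        p = rx.FlowParams(A_f=0.0)
        snap = rx.shear_decompose(p, grid, 0.0)
        part = rx.decile_partition(snap, source="gy")  # gy monotone in y
        binmap = part.bin_index.reshape(100, 100)
        assert np.all(binmap == binmap[:, :1])  # horizontal bands

    def test_indivisible_grid_rejected(self, flow):
        snap = rx.shear_decompose(flow, rx.GridSpec(nx=33, ny=3), 0.0)
        with pytest.raises(ValueError):
            rx.decile_partition(snap)


class TestNormalizedCount:
    def test_conservation_over_bins(self, flow, grid):
        rng = np.random.default_rng(3)
        n = 200
        pos = np.column_stack(
            [rng.uniform(0, L, n), rng.uniform(-H / 2 + R, H / 2 - R, n)]
        )
        snap = rx.shear_decompose(flow, grid, 0.0)
        part = rx.decile_partition(snap, source="gmag")
        flags, _, _ = rx.detect_aggregated(state_from(pos), R, L, H)
        counts = rx.normalized_count(pos, part, flags, flow, grid)
        assert counts.min() >= 0
        assert np.sum(counts * (n / 10)) == pytest.approx(flags.sum())

    def test_all_aggregated_uniform_is_near_one(self, flow, grid):
        # dense uniform lattice, everything flagged: every bin close to 1
        xs, ys = np.meshgrid(
            np.linspace(0, L, 100, endpoint=False),
            np.linspace(-H / 2 + R, H / 2 - R, 50),
        )
        pos = np.column_stack([xs.ravel(), ys.ravel()])
        snap = rx.shear_decompose(flow, grid, 0.0)
        part = rx.decile_partition(snap, source="gy")
        flags = np.ones(len(pos), dtype=bool)
        counts = rx.normalized_count(pos, part, flags, flow, grid)
        assert counts.mean() == pytest.approx(1.0, rel=1e-12)
        assert np.all(np.abs(counts - 1) < 0.25)

    def test_rectangle_baseline_area_ratio(self, flow, grid):
        # 0.1 x 0.1 mm^2 ROI with N = 533: baseline 533/6 = 88.83
        part = rx.rectangle_roi(flow)
        assert analysis._baselines(part, flow, 533)[0] == pytest.approx(88.83, abs=0.01)

    def test_empty_bin_is_zero(self, flow, grid):
        pos = np.array([[L / 2, 0.0]])
        part = rx.rectangle_roi(flow, width=1e-5, height=1e-5, center=(1e-5, -5e-5))
        counts = rx.normalized_count(pos, part, np.array([True]), flow, grid)
        assert counts[0] == 0.0

    def test_rectangle_outside_tube_rejected(self, flow):
        with pytest.raises(ValueError):
            rx.rectangle_roi(flow, width=0.2e-3, height=0.2e-3)


class TestRoiMeanShear:
    def test_constant_field_returns_constant(self, flow, grid):
        snap = rx.shear_decompose(flow, grid, 0.0)
        const = rx.ShearFieldSnapshot(
            t=0.0, u=snap.u, gx=snap.gx, gy=snap.gy,
            gmag=np.full_like(snap.gmag, 3.7), phi=snap.phi,
        )
        part = rx.decile_partition(snap, source="gy")
        np.testing.assert_allclose(rx.roi_mean_shear(const, part, flow, grid), 3.7)

    def test_poiseuille_rectangle_against_analytic_integral(self, grid):
        """Steady-flow |gy| averaged over a centered band: the cell-center
        quadrature must match the exact integral mean 2*B_f*b*4/h^2 / 2 of
        |8*y*B_f/h^2| over |y| <= b to grid accuracy."""
        p = rx.FlowParams(A_f=0.0, B_f=4e-3)
        rect = rx.rectangle_roi(p, width=0.1e-3, height=0.06e-3)
        snap = rx.shear_decompose(p, grid, 0.0)
        got = rx.roi_mean_shear(snap, rect, p, grid)[0]
        b = 0.03e-3
        exact = 8 * p.B_f / p.h**2 * b / 2  # mean |y| over [-b, b] is b/2
        assert got == pytest.approx(exact, rel=2e-4)

    def test_nonnegative(self, flow, grid):
        snap = rx.shear_decompose(flow, grid, 0.1)
        part = rx.decile_partition(snap, source="gmag")
        assert np.all(rx.roi_mean_shear(snap, part, flow, grid) >= 0)


class TestHysteresis:
    def test_unit_circle_area_pi(self):
        # x = cos, y = sin traced counterclockwise: shoelace area -> +pi
        times = np.linspace(0, 5, 1000, endpoint=False)
        x = np.cos(2 * np.pi * times)
        y = np.sin(2 * np.pi * times)
        curve = rx.hysteresis(times, x, y, f=1.0, n_cycles=5, n_phase=40)
        assert curve.area == pytest.approx(np.pi, rel=0.01)
        # identical cycles: only bin-edge rounding jitter contributes
        assert np.all(curve.x_sd < 0.01)

    def test_degenerate_loop_zero_area(self):
        times = np.linspace(0, 5, 500, endpoint=False)
        x = np.cos(2 * np.pi * times)
        curve = rx.hysteresis(times, x, x, f=1.0, n_cycles=5)
        assert curve.area == pytest.approx(0.0, abs=1e-12)

    def test_too_few_cycles_rejected(self):
        times = np.linspace(0, 2, 100)
        with pytest.raises(ValueError):
            rx.hysteresis(times, times, times, f=1.0, n_cycles=5)

    def test_steady_quantity_zero_area(self, small_traj):
        times = small_traj.times
        x = np.full_like(times, 2.0)
        y = np.sin(2 * np.pi * times)
        curve = rx.hysteresis(times, x, y, f=1.0, n_cycles=1)
        assert curve.area == pytest.approx(0.0, abs=1e-12)


class TestTrajectoryMetrics:
    def test_decile_metrics_layout(self, small_traj):
        df = rx.decile_metrics(small_traj, source="gx", phase=0.9)
        assert set(df["roi_id"]) == set(range(10))
        assert len(df) == 10 * small_traj.config.n_cycles
        assert (df["roi_source"] == "gx").all()

    def test_peak_normalized_count_bounds(self, small_traj):
        peak = rx.peak_normalized_count(small_traj)
        assert 0 <= peak <= small_traj.config.N / (small_traj.config.N / 10)

    def test_aggregation_timeseries(self, small_traj):
        ts = analysis.aggregation_timeseries(small_traj)
        assert len(ts) == small_traj.n_snapshots
        assert (ts["n_aggregated"] >= 0).all()
        assert (ts["MAS"] >= 0).all()
        # components of size >= 2 cannot outnumber half the flagged particles
        nz = ts[ts["n_aggregated"] > 0]
        assert (nz["MAS"] >= 2).all()
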