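"""Motility-statistics unit tests (MSD, persistence, radial speed,
cluster metrics)."""

import numpy as np
import pandas as pd
import pytest

from senoclust.lattice import CellTable, Lattice
from senoclust.synth import gen_inward_tracks
from senoclust.tracks import (
    PersistenceCurve,
    cluster_metrics,
    compute_msd,
    direction_autocorr,
    fit_msd_exponent,
    fit_two_exponential,
    radial_velocity,
    validate_tracks,
)


def table(positions, dt=1.0):
    """(n_tracks, n_frames, 2|3) array -> tidy track table."""
    rows = []
    for cid, track in enumerate(positions):
        for k, p in enumerate(track):
            z = p[2] if len(p) > 2 else 0.0
            rows.append((cid, k * dt, p[0], p[1], z))
    return pd.DataFrame(rows, columns=["cell_id", "time", "x", "y", "z"])


def ballistic(v=3.0, n=50):
    t = np.arange(n, dtype=float)
    return np.stack([v * t, np.zeros(n)], axis=1)[None]


class TestMsd:
    def test_ballistic_exact(self):
        df = table(ballistic())
        msd = compute_msd(df)
        assert msd.msd[0] == 0.0
        assert np.allclose(msd.msd[1:], 9.0 * msd.lags[1:] ** 2)
        alpha, se = fit_msd_exponent(msd)
        assert alpha == pytest.approx(2.0, abs=1e-3)
        assert se < 1e-3

    def test_stationary_all_zero(self):
        df = table(np.zeros((3, 30, 2)))
        msd = compute_msd(df)
        assert np.allclose(msd.msd, 0.0)

    def test_brownian_slope_one(self):
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.standard_normal((100, 2000, 2)), axis=1)
        alpha, _ = fit_msd_exponent(compute_msd(table(pos)))
        assert alpha == pytest.approx(1.0, abs=0.05)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        pos = np.cumsum(rng.standard_normal((5, 200, 2)), axis=1)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pos @ R.T + np.array([120.0, -40.0])
        m1 = compute_msd(table(pos))
        m2 = compute_msd(table(moved))
        assert np.allclose(m1.msd, m2.msd, rtol=1e-9)

    def test_unit_rescaling_leaves_alpha(self):
        rng = np.random.default_rng(2)
        pos = np.cumsum(rng.standard_normal((20, 500, 2)), axis=1)
        a1, _ = fit_msd_exponent(compute_msd(table(pos, dt=1.0)))
        a2, _ = fit_msd_exponent(compute_msd(table(pos * 37.0, dt=0.25)))
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_non_uniform_sampling_rejected(self):
        df = table(ballistic())
        df.loc[df.index[-1], "time"] += 0.5
        with pytest.raises(ValueError):
            compute_msd(df)


class TestDirectionAutocorr:
    def test_straight_line_fully_persistent(self):
        pc = direction_autocorr(table(ballistic()))
        assert np.allclose(pc.values, 1.0)

    def test_zigzag_orthogonal_headings(self):
        # alternate +x, +y steps: headings 90 degrees apart at lag 1
        steps = np.array([[1.0, 0.0], [0.0, 1.0]] * 20)
        pos = np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)])[None]
        pc = direction_autocorr(table(pos))
        assert pc.values[1] == pytest.approx(0.0, abs=1e-12)
        assert pc.values[2] == pytest.approx(1.0)

    def test_isotropic_headings_decorrelate(self):
        rng = np.random.default_rng(3)
        ang = rng.uniform(0, 2 * np.pi, (40, 400))
        steps = np.stack([np.cos(ang), np.sin(ang)], axis=2)
        pos = np.concatenate([np.zeros((40, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
        pc = direction_autocorr(table(pos), max_lag=20)
        assert pc.values[0] == 1.0
        assert np.all(np.abs(pc.values[1:]) < 0.05)

    def test_values_bounded(self):
        rng = np.random.default_rng(4)
        pos = np.cumsum(rng.standard_normal((10, 100, 2)), axis=1)
        pc = direction_autocorr(table(pos))
        assert np.nanmax(np.abs(pc.values)) <= 1.0 + 1e-12

    def test_zero_displacement_skipped(self):
        pos = np.zeros((1, 20, 2))
        pos[0, 10:, 0] = np.arange(10)  # still for 10 frames, then moves
        pc = direction_autocorr(table(pos), max_lag=3)
        assert np.all(np.isfinite(pc.values[:3]))


def forward_curve(A, tau, B, tau0, dt=0.25, n=100):
    lags = np.arange(n) * dt
    vals = A * np.exp(-lags / tau) + B * np.exp(-lags / tau0)
    vals[0] = 1.0
    return PersistenceCurve(
        lags=lags, values=vals, sd=np.zeros(n), n_tracks=1, dt=dt
    )


class TestTwoExponentialFit:
    @pytest.mark.parametrize(
        "A,tau,B,tau0",
        [
            (0.14, 4.56, 0.64, 0.38),  # the published autocorrelation fit
            (0.5, 10.0, 0.5, 1.0),
            (0.2, 25.0, 0.8, 0.5),
            (0.9, 2.0, 0.1, 1.0),
            (0.3, 40.0, 0.3, 5.0),
        ],
    )
    def test_exact_inversion_of_forward_curves(self, A, tau, B, tau0):
        fit = fit_two_exponential(forward_curve(A, tau, B, tau0))
        assert fit.A == pytest.approx(A, abs=1e-6)
        assert fit.tau == pytest.approx(tau, abs=1e-5)
        assert fit.B == pytest.approx(B, abs=1e-6)
        assert fit.tau0 == pytest.approx(tau0, abs=1e-6)
        assert fit.tau > fit.tau0 > 0

    def test_single_exponential_nested(self):
        fit = fit_two_exponential(forward_curve(0.7, 5.0, 0.0, 0.5))
        # either amplitude may carry the component; the slow constant wins
        main_tau = fit.tau if fit.A > fit.B else fit.tau0
        main_amp = max(fit.A, fit.B)
        assert main_amp == pytest.approx(0.7, abs=1e-4)
        assert main_tau == pytest.approx(5.0, abs=1e-3)

    def test_pure_noise_flagged(self):
        rng = np.random.default_rng(0)
        n = 60
        curve = PersistenceCurve(
            lags=np.arange(n) * 0.25,
            values=np.concatenate([[1.0], rng.normal(0, 0.02, n - 1)]),
            sd=np.zeros(n),
            n_tracks=1,
            dt=0.25,
        )
        fit = fit_two_exponential(curve)
        assert not fit.ok

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_two_exponential(forward_curve(0.5, 5.0, 0.3, 1.0, n=5))


class TestRadialVelocity:
    def test_straight_inward(self):
        df = gen_inward_tracks((0.0, 0.0), speed=40.0, n_tracks=5, rng=0)
        assert radial_velocity(df, (0.0, 0.0)) == pytest.approx(40.0, abs=1e-9)

    def test_circular_orbit_zero(self):
        t = np.arange(60) * 0.1
        pos = 50.0 * np.stack([np.cos(t), np.sin(t)], axis=1)[None]
        assert radial_velocity(table(pos), (0.0, 0.0)) == pytest.approx(0.0, abs=1e-9)

    def test_noisy_ensemble_recovers_mean(self):
        # per-track speeds N(38.7, 10): the ensemble mean converges by CLT
        df = gen_inward_tracks(
            (0.0, 0.0), speed=38.7, speed_sd=10.0, n_tracks=50,
            noise_sd=1.0, rng=np.random.default_rng(5),
        )
        assert radial_velocity(df, (0.0, 0.0)) == pytest.approx(38.7, abs=3.0)


class TestClusterMetrics:
    def build(self, with_tumor_on_core):
        lat = Lattice((20, 20, 12))
        cells = CellTable()
        mid = cells.new_cell("matrix")
        lat.grid[:, :, 0] = mid
        core = cells.new_cell("core", target_volume=100.0)
        lat.grid[8:13, 8:13, 1:5] = core
        body = cells.new_cell("body", target_volume=50.0)
        lat.grid[5:8, 8:13, 1:3] = body
        if with_tumor_on_core:
            t1 = cells.new_cell("tumor", target_volume=8.0)
            lat.grid[9:11, 9:11, 5:7] = t1
            t2 = cells.new_cell("tumor", target_volume=8.0)
            lat.grid[9:11, 9:11, 7:9] = t2
        else:
            t1 = cells.new_cell("tumor", target_volume=8.0)
            lat.grid[1:3, 1:3, 1:3] = t1  # far from the core, on the floor
        lat.sync_caches(cells)
        return lat, cells

    def test_no_cells_above_body(self):
        lat, cells = self.build(False)
        cm = cluster_metrics(lat, cells)
        assert (cm.n_cells_on_core, cm.max_stack_height, cm.cluster_formed) == (
            0, 0, False,
        )

    def test_two_stacked_cells_form_cluster(self):
        lat, cells = self.build(True)
        cm = cluster_metrics(lat, cells)
        assert cm.n_cells_on_core == 2
        assert cm.max_stack_height == 4  # z = 5..8 contiguous over the core
        assert cm.cluster_formed

    def test_missing_core_raises(self):
        lat = Lattice((8, 8, 4))
        cells = CellTable()
        lat.sync_caches(cells)
        with pytest.raises(ValueError):
            cluster_metrics(lat, cells)


class TestTrackValidation:
    def test_duplicate_rows_rejected(self):
        df = table(ballistic())
        dup = pd.concat([df, df.iloc[[0]]])
        with pytest.raises(ValueError):
            validate_tracks(dup)
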