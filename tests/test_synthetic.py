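"""Generators: Brownian moments, state labels, rendering, OU statistics."""

import numpy as np
import pytest

from cytodyn.synthetic import (
    FilamentShape,
    MotorParams,
    TwoStateDiffusionParams,
    ornstein_uhlenbeck,
    render_spots,
    simulate_filament_kymograph,
    simulate_run_trajectory,
    simulate_two_state,
)
from cytodyn.trajectory import Trajectory

from conftest import random_filament


class TestTwoState:
    def test_zero_diffusion_zero_noise_is_static(self):
        p = TwoStateDiffusionParams(d_fast=1e-300, d_slow=0.0, sigma_loc=0.0)
        (tr,) = simulate_two_state(p, 1, 50, seed=0)
        assert np.allclose(tr.x, tr.x[0]) and np.allclose(tr.y, tr.y[0])

    def test_single_frame_msd_matches_brownian_moment(self):
        # closed form: E|dr|^2 over one frame = 4 D dt per 2D step
        d, dt = 2.5, 0.0024
        p = TwoStateDiffusionParams(d_fast=d, d_slow=0.0, p_fast0=1.0,
                                    sigma_loc=0.0, dt=dt)
        tracks = simulate_two_state(p, 500, 66, seed=3)
        sq = np.concatenate([
            np.sum(np.diff(tr.positions, axis=0) ** 2, axis=1) for tr in tracks])
        expect = 4 * d * dt
        se = sq.std() / np.sqrt(len(sq))
        assert abs(sq.mean() - expect) < 3 * se

    def test_msd_matches_4dtau_up_to_quarter_track(self):
        from cytodyn.diffusion import ensemble_msd, msd_track

        d, dt = 1.0, 0.01
        p = TwoStateDiffusionParams(d_fast=d, d_slow=0.0, p_fast0=1.0,
                                    sigma_loc=0.0, dt=dt)
        tracks = simulate_two_state(p, 400, 64, seed=4)
        ens = ensemble_msd([msd_track(tr, 0.25) for tr in tracks])
        for tau, m, n in zip(ens.delays, ens.msd, ens.n_pairs):
            se = m * np.sqrt(2.0 / n)  # chi2 scale upper bound on the se
            assert abs(m - 4 * d * tau) < 3 * se + 0.05 * 4 * d * tau

    def test_paper_parameters_give_bimodal_msd1(self):
        p = TwoStateDiffusionParams(d_fast=10.1, d_slow=0.06, p_fast0=0.5,
                                    sigma_loc=0.0175, dt=0.0024)
        tracks = simulate_two_state(p, 300, 66, seed=5)
        msd1 = np.array([
            np.mean(np.sum(np.diff(tr.positions, axis=0) ** 2, axis=1))
            for tr in tracks])
        # two-threshold check: modes on both sides of a dead zone between them
        low = 4 * 0.06 * 0.0024 + 4 * 0.0175**2  # expected slow msd1
        high = 4 * 10.1 * 0.0024  # expected fast msd1
        mid = np.sqrt(low * high)
        assert np.mean(msd1 < mid) > 0.3
        assert np.mean(msd1 > mid) > 0.3
        assert np.mean((msd1 > 3 * low) & (msd1 < high / 3)) < 0.05

    def test_state_switching_produces_both_labels(self):
        p = TwoStateDiffusionParams(d_fast=1.0, d_slow=0.01, k_fs=20.0,
                                    k_sf=20.0, dt=0.01, sigma_loc=0.0)
        tracks = simulate_two_state(p, 10, 200, seed=6)
        labels = np.concatenate([tr.state for tr in tracks])
        assert set(labels) == {"fast", "slow"}

    def test_blinking_leaves_gaps_with_true_frame_indices(self):
        p = TwoStateDiffusionParams(d_fast=1.0, d_slow=0.0, p_fast0=1.0,
                                    dt=0.01, blink_on_mean=0.05,
                                    blink_off_mean=0.05)
        tracks = simulate_two_state(p, 20, 200, seed=7)
        assert any(tr.has_gaps for tr in tracks)
        for tr in tracks:
            assert np.all(np.diff(tr.frames) > 0)
            assert np.allclose(tr.t, tr.frames * 0.01)

    def test_rejects_nonfinite_parameters(self):
        with pytest.raises(ValueError):
            TwoStateDiffusionParams(d_fast=np.nan)
        with pytest.raises(ValueError):
            TwoStateDiffusionParams(d_fast=0.5, d_slow=1.0)

    def test_determinism_per_seed(self):
        p = TwoStateDiffusionParams()
        a = simulate_two_state(p, 5, 30, seed=42)
        b = simulate_two_state(p, 5, 30, seed=42)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.x, tb.x) and np.array_equal(ta.y, tb.y)
            assert np.array_equal(ta.frames, tb.frames)


class TestRunTrajectory:
    def test_straight_filament_constant_speed(self):
        verts = np.column_stack([np.linspace(0, 20, 21), np.zeros(21)])
        shape = FilamentShape(verts, undulation_sd=0.0)
        motor = MotorParams(speed_mean=1.0, speed_sd=0.0,
                            run_duration_mean=15.0, off_duration_mean=1.0,
                            sigma_loc=0.0, dt=0.05)
        tr = simulate_run_trajectory(shape, motor, 50, seed=1)
        # assert over the initial bound episode (exponential duration)
        n_bound = int(np.argmin(tr.state == "bound")) or len(tr)
        assert n_bound >= 20
        steps = np.linalg.norm(np.diff(tr.positions[:n_bound], axis=0), axis=1)
        assert np.allclose(steps, 1.0 * 0.05, atol=1e-9)
        assert np.allclose(tr.y[:n_bound], 0.0, atol=1e-9)

    def test_arc_length_traveled_matches_speed_on_circle(self):
        # independent oracle: chord sum of a circular arc traveled at v
        R = 5.0
        th = np.linspace(0, 1.6 * np.pi, 40)
        shape = FilamentShape(R * np.column_stack([np.cos(th), np.sin(th)]),
                              undulation_sd=0.0)
        motor = MotorParams(speed_mean=1.0, speed_sd=0.0,
                            run_duration_mean=20.0, off_duration_mean=1.0,
                            sigma_loc=0.0, dt=0.05)
        n = 100
        tr = simulate_run_trajectory(shape, motor, n, seed=2)
        n_bound = int(np.argmin(tr.state == "bound")) or len(tr)
        assert n_bound >= 50
        arc = np.sum(np.linalg.norm(
            np.diff(tr.positions[:n_bound], axis=0), axis=1))
        expected = motor.speed_mean * (n_bound - 1) * motor.dt
        assert arc == pytest.approx(expected, rel=0.01)

    def test_labels_partition_frames(self):
        rng = np.random.default_rng(0)
        shape = random_filament(rng)
        motor = MotorParams(run_duration_mean=1.0, off_duration_mean=0.5)
        tr = simulate_run_trajectory(shape, motor, 150, seed=3)
        assert set(np.unique(tr.state)) <= {"bound", "unbound"}
        assert len(tr.state) == len(tr)

    def test_filament_shorter_than_expected_run_rejected(self):
        verts = np.column_stack([np.linspace(0, 1.5, 5), np.zeros(5)])
        shape = FilamentShape(verts)
        motor = MotorParams(speed_mean=2.5, run_duration_mean=4.0)
        with pytest.raises(ValueError):
            simulate_run_trajectory(shape, motor, 10, seed=0)


class TestOrnsteinUhlenbeck:
    def test_autocorrelation_decay(self):
        sd, tau, dt = 0.5, 2.0, 0.1
        rng = np.random.default_rng(8)
        x = ornstein_uhlenbeck(200_000, sd, tau, dt, rng)
        for k in (1, 5, 10):
            emp = np.mean(x[:-k] * x[k:]) / np.mean(x * x)
            assert emp == pytest.approx(np.exp(-k * dt / tau), abs=0.02)

    def test_stationary_variance(self):
        rng = np.random.default_rng(9)
        x = ornstein_uhlenbeck(100_000, 0.3, 1.0, 0.5, rng)
        assert x.std() == pytest.approx(0.3, rel=0.03)


class TestRenderSpots:
    def test_zero_photons_pure_background(self):
        tr = Trajectory(0, [0], [0.0], [1.0], [1.0])
        stack = render_spots([tr], psf_sigma=0.15, photons=0, background=7.0,
                             pixel_size=0.1, noise_seed=1, shape=(24, 24))
        vals = stack.intensity.ravel()
        assert vals.mean() == pytest.approx(7.0, rel=0.1)
        assert vals.var() == pytest.approx(7.0, rel=0.2)  # Poisson

    def test_noiseless_centroid_equals_position(self):
        tr = Trajectory(0, [0], [0.0], [1.234], [1.567])
        stack = render_spots([tr], psf_sigma=0.15, photons=1000, background=0,
                             pixel_size=0.1, noise_seed=None, shape=(32, 32))
        img = stack.intensity[0]
        ii, jj = np.mgrid[0:32, 0:32]
        tot = img.sum()
        cx = ((jj + 0.5) * 0.1 * img).sum() / tot
        cy = ((ii + 0.5) * 0.1 * img).sum() / tot
        assert cx == pytest.approx(1.234, abs=1e-6)
        assert cy == pytest.approx(1.567, abs=1e-6)

    def test_undersampled_psf_warns(self):
        tr = Trajectory(0, [0], [0.0], [1.0], [1.0])
        with pytest.warns(UserWarning):
            render_spots([tr], psf_sigma=0.01, photons=10, background=0,
                         pixel_size=0.1, shape=(16, 16))

    def test_out_of_field_position_rejected(self):
        tr = Trajectory(0, [0], [0.0], [99.0], [1.0])
        with pytest.raises(ValueError):
            render_spots([tr], psf_sigma=0.15, photons=10, background=0,
                         pixel_size=0.1, shape=(16, 16))


class TestFilamentKymograph:
    def test_frozen_dynamics_static_columns(self):
        kymo, _ = simulate_filament_kymograph(
            2, d_fluct=0.0, l_conf=0.4, psf_sigma=0.15, pixel_size=0.1,
            dt=1.0, n_frames=30, seed=1)
        assert np.allclose(kymo.intensity, kymo.intensity[:, [0]])

    def test_ridge_variance_matches_ou_stationary_variance(self):
        l_conf = 0.4
        kymo, centers = simulate_filament_kymograph(
            1, d_fluct=0.01, l_conf=l_conf, psf_sigma=0.15, pixel_size=0.1,
            dt=1.0, n_frames=4000, seed=2)
        x = centers[0] - centers[0].mean()
        var_expect = l_conf**2 / 12.0
        # 3 s.e. of the variance of an AR(1) series, effective sample size
        tau_frames = (l_conf**2 / 12.0) / 0.01
        n_eff = len(x) / (2 * tau_frames)
        se = var_expect * np.sqrt(2.0 / n_eff)
        assert abs(np.var(x) - var_expect) < 3 * se

    def test_invalid_confinement_rejected(self):
        with pytest.raises(ValueError):
            simulate_filament_kymograph(1, d_fluct=0.01, l_conf=0.0,
                                        psf_sigma=0.15, pixel_size=0.1,
                                        dt=1.0, n_frames=20, seed=0)
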