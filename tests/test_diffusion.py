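"""MSD estimation, classification, and derived physical quantities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytodyn.diffusion import (
    MSDCurve,
    classify_mobility,
    density_by_class,
    ensemble_diffusion,
    ensemble_msd,
    estimate_pore_size,
    fit_diffusion,
    msd_track,
    renkin_hindrance,
    stokes_einstein_d,
    trapping_timescale,
    velocity_autocorrelation,
    viscosity_ratio,
)
from cytodyn.synthetic import TwoStateDiffusionParams, simulate_two_state
from cytodyn.trajectory import Trajectory

from conftest import static_track


def brute_force_msd(traj: Trajectory):
    """O(n²) oracle: average squared displacement per true time delay."""
    acc = {}
    pos = traj.positions
    for i in range(len(traj)):
        for j in range(i + 1, len(traj)):
            tau = round(float(traj.t[j] - traj.t[i]), 12)
            acc.setdefault(tau, []).append(float(np.sum((pos[j] - pos[i]) ** 2)))
    taus = sorted(acc)
    return (np.array(taus), np.array([np.mean(acc[t]) for t in taus]),
            np.array([len(acc[t]) for t in taus]))


class TestMSD:
    def test_static_track_msd_zero(self):
        curve = msd_track(static_track())
        assert np.allclose(curve.msd, 0.0)

    def test_ballistic_track_quadratic(self):
        v, dt, n = 1.7, 0.05, 30
        t = np.arange(n) * dt
        tr = Trajectory(0, np.arange(n), t, v * t, np.zeros(n))
        curve = msd_track(tr)
        assert np.allclose(curve.msd, (v * curve.delays) ** 2, rtol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 25))
        frames = np.sort(rng.choice(np.arange(3 * n), size=n, replace=False))
        tr = Trajectory(0, frames, frames * 0.01,
                        rng.normal(size=n), rng.normal(size=n))
        curve = msd_track(tr)
        taus, msds, counts = brute_force_msd(tr)
        assert np.allclose(curve.delays, taus, atol=1e-9)
        assert np.allclose(curve.msd, msds, atol=1e-12)
        assert np.array_equal(curve.n_pairs, counts)

    def test_ensemble_identity_and_weighted_mean(self):
        c = MSDCurve([0.1], [4.0], [3])
        assert ensemble_msd([c]).msd[0] == 4.0
        c2 = MSDCurve([0.1], [0.0], [1])
        assert ensemble_msd([c, c2]).msd[0] == pytest.approx(3.0)

    def test_ensemble_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_msd([])

    def test_ensemble_slope_recovers_d(self):
        p = TwoStateDiffusionParams(d_fast=1.0, d_slow=0.0, p_fast0=1.0,
                                    sigma_loc=0.0, dt=0.01)
        tracks = simulate_two_state(p, 300, 64, seed=10)
        est = ensemble_diffusion([msd_track(tr) for tr in tracks], 0.25)
        assert abs(est.d - 1.0) < 3 * est.stderr_d
        assert abs(est.d - 1.0) / 1.0 < 0.1


class TestFitDiffusion:
    def test_exact_line(self):
        tau = np.arange(1, 21) * 0.01
        est = fit_diffusion(MSDCurve(tau, 4 * 2.5 * tau, np.ones(20)), 0.25)
        assert est.d == pytest.approx(2.5, abs=1e-12)
        assert est.offset_dx2 == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_with_offset_35nm(self):
        tau = np.arange(1, 21) * 0.0024
        offset = 0.001225  # (35 nm)^2 in µm²
        curve = MSDCurve(tau, 4 * 0.06 * tau + offset, np.ones(20))
        est = fit_diffusion(curve, 0.25)
        assert est.d == pytest.approx(0.06, rel=1e-9)
        assert est.offset_dx2 == pytest.approx(offset, rel=1e-9)

    def test_forced_zero_offset(self):
        tau = np.arange(1, 11) * 0.01
        est = fit_diffusion(MSDCurve(tau, 4 * 1.5 * tau, np.ones(10)),
                            1.0, with_offset=False)
        assert est.offset_dx2 == 0.0
        assert est.d == pytest.approx(1.5, rel=1e-12)

    def test_estimator_unbiased_with_calibrated_errors(self):
        # 50 replicate ensembles at D=1: mean within 2%, 2-sigma coverage >= 90%
        p = TwoStateDiffusionParams(d_fast=1.0, d_slow=0.0, p_fast0=1.0,
                                    sigma_loc=0.0, dt=0.0024)
        est, cover = [], 0
        for rep in range(50):
            tracks = simulate_two_state(p, 200, 64, seed=rep)
            e = ensemble_diffusion([msd_track(tr) for tr in tracks], 0.25)
            est.append(e.d)
            cover += abs(e.d - 1.0) <= 2 * e.stderr_d
        assert abs(np.mean(est) - 1.0) < 0.02
        assert cover >= 45


class TestClassification:
    def test_static_track_is_slow(self):
        labels, _ = classify_mobility([static_track()], threshold_msd1=0.01)
        assert labels[0].label == "slow"

    def test_well_separated_populations_misclassification_below_2pct(self):
        p = TwoStateDiffusionParams(d_fast=10.1, d_slow=0.06, p_fast0=0.5,
                                    sigma_loc=0.0175, dt=0.0024)
        tracks = simulate_two_state(p, 400, 66, seed=5)
        labels, thr = classify_mobility(tracks, "auto")
        truth = np.array([tr.state[0] for tr in tracks])
        pred = np.array([lab.label for lab in labels])
        assert np.mean(pred != truth) < 0.02
        assert 0.001 < thr < 0.05  # dip sits between the two modes

    def test_error_monotone_in_d_ratio(self):
        errs = []
        for d_slow in (1.0, 0.3, 0.01):  # ratios 10x, 33x, 1000x
            p = TwoStateDiffusionParams(d_fast=10.0, d_slow=d_slow,
                                        p_fast0=0.5, sigma_loc=0.0, dt=0.0024)
            tracks = simulate_two_state(p, 300, 66, seed=8)
            thr = np.sqrt((4 * 10.0 * 0.0024) * (4 * d_slow * 0.0024))
            labels, _ = classify_mobility(tracks, thr)
            truth = np.array([tr.state[0] for tr in tracks])
            pred = np.array([lab.label for lab in labels])
            errs.append(np.mean(pred != truth))
        assert errs[0] >= errs[1] >= errs[2]

    def test_unimodal_auto_threshold_raises(self):
        p = TwoStateDiffusionParams(d_fast=1.0, d_slow=0.0, p_fast0=1.0,
                                    sigma_loc=0.0, dt=0.01)
        tracks = simulate_two_state(p, 100, 30, seed=9)
        with pytest.raises(ValueError, match="threshold"):
            classify_mobility(tracks, "auto")


class TestVelocityAutocorrelation:
    def test_ballistic_normalized_one(self):
        n = 30
        t = np.arange(n) * 0.1
        tr = Trajectory(0, np.arange(n), t, 2.0 * t, -1.0 * t)
        vac = velocity_autocorrelation(tr, max_lag=10)
        assert np.allclose(vac.vac_normalized, 1.0, atol=1e-9)

    def test_brownian_uncorrelated_beyond_lag_zero(self):
        p = TwoStateDiffusionParams(d_fast=1.0, d_slow=0.0, p_fast0=1.0,
                                    sigma_loc=0.0, dt=0.01)
        (tr,) = simulate_two_state(p, 1, 5000, seed=11)
        vac = velocity_autocorrelation(tr, max_lag=3)
        for lag in (1, 2, 3):
            i = int(np.where(vac.lags == lag)[0][0])
            se = vac.vac[0] / np.sqrt(vac.n_pairs[i])
            assert abs(vac.vac[i]) < 3 * se

    def test_noise_only_anticorrelation_minus_half(self):
        # closed form: VAC(1)/VAC(0) = -1/2 for pure localization noise
        rng = np.random.default_rng(12)
        n = 20000
        tr = Trajectory(0, np.arange(n), np.arange(n) * 0.01,
                        rng.normal(0, 0.02, n), rng.normal(0, 0.02, n))
        vac = velocity_autocorrelation(tr, max_lag=1)
        assert vac.vac_normalized[1] == pytest.approx(-0.5, abs=0.02)


class TestDerivedQuantities:
    def test_density_conservation_and_paper_example(self):
        from cytodyn.diffusion import MobilityLabel

        labels = [MobilityLabel(i, 1.0, "fast") for i in range(11)]
        dens = density_by_class(labels, 100.0)
        assert dens["fast"] == pytest.approx(0.11)
        labels += [MobilityLabel(100 + i, 1e-4, "slow") for i in range(5)]
        dens = density_by_class(labels, 100.0)
        assert dens["fast"] + dens["slow"] == pytest.approx(16 / 100.0)
        assert density_by_class([], 50.0) == {"fast": 0.0, "slow": 0.0}

    def test_stokes_einstein_scaling_and_magnitude(self):
        d1 = stokes_einstein_d(0.0144)  # 14.4 nm radius, water at 25 C
        assert d1 == pytest.approx(17.0, rel=0.02)
        assert stokes_einstein_d(0.0288) == pytest.approx(d1 / 2, rel=1e-12)

    def test_viscosity_ratio(self):
        assert viscosity_ratio(16.0, 10.1) == pytest.approx(1.584, abs=0.001)
        assert viscosity_ratio(5.0, 5.0) == 1.0
        assert viscosity_ratio(16.0, 5.05) == pytest.approx(2 * 16.0 / 10.1)

    def test_pore_size_round_trip_inversion(self):
        probe = 0.028
        for pore_true in (0.036, 0.05, 0.3):
            ratio = renkin_hindrance(probe / pore_true)
            res = estimate_pore_size(ratio, probe)
            assert res["pore_diameter"] == pytest.approx(pore_true, abs=1e-6)

    def test_pore_size_near_unity_ratio_rejected(self):
        with pytest.raises(ValueError):
            estimate_pore_size(0.9999999, 0.028)

    def test_pore_size_reproduces_mesh_scale(self):
        res = estimate_pore_size(0.006, 0.028)
        assert res["pore_diameter"] == pytest.approx(0.036, rel=0.2)

    def test_trapping_timescale_variants(self):
        out = trapping_timescale(0.036, 0.028, 10.0)
        assert out["printed_variant"] == pytest.approx(6.4e-6, rel=1e-9)
        assert out["six_d_denominator"] == pytest.approx(1.0667e-6, rel=1e-3)
        zero = trapping_timescale(0.028, 0.028, 10.0)
        assert zero["six_d_denominator"] == 0.0
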