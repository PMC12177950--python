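import numpy as np
import pytest

from trapdiff.msd import (
    DwellSet,
    JumpDistanceDistribution,
    MobilityTrace,
    MSDCurve,
    dwell_times,
    ensemble_msd,
    fit_anomalous,
    fit_lognormal,
    fit_two_component_jumps,
    jump_distances,
    mobility_states,
    msd_time_averaged,
    temporal_diffusion,
    temporal_msd,
    temporal_weights,
)
from trapdiff.trajectories import Trajectory, TrajectorySet

from conftest import brownian_set, brownian_trajectory


class TestTimeAveragedMSD:
    def test_hand_sum_unit_jumps(self, simple_track):
        # (0,0)->(1,0)->(1,1): two unit jumps at lag 1
        assert msd_time_averaged(simple_track, 1) == pytest.approx(1.0)

    def test_hand_sum_lag_two(self, simple_track):
        assert msd_time_averaged(simple_track, 2) == pytest.approx(2.0)

    def test_stationary_is_zero(self):
        t = Trajectory(0, np.arange(10), np.full(10, 3.0), np.full(10, -2.0), 0.1)
        for n in (1, 5, 9):
            assert msd_time_averaged(t, n) == 0.0

    def test_lag_out_of_range_raises(self, simple_track):
        with pytest.raises(ValueError):
            msd_time_averaged(simple_track, 3)

    def test_gapped_track_rejected(self):
        t = Trajectory(0, [0, 1, 3], [0, 1, 2], [0, 0, 0], 0.1)
        with pytest.raises(ValueError, match="gap"):
            msd_time_averaged(t, 1)

    def test_rigid_motion_invariance_and_quadratic_scaling(self, rng):
        t = brownian_trajectory(rng, 30, 0.5, 0.1)
        base = msd_time_averaged(t, 3)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = t.positions @ R.T + [5.0, -3.0]
        moved = Trajectory(0, t.frames, rot[:, 0], rot[:, 1], 0.1)
        assert msd_time_averaged(moved, 3) == pytest.approx(base, rel=1e-12)
        scaled = Trajectory(0, t.frames, 3.0 * t.x, 3.0 * t.y, 0.1)
        assert msd_time_averaged(scaled, 3) == pytest.approx(9.0 * base, rel=1e-12)


class TestEnsembleMSD:
    def test_identical_tracks_equal_single(self, rng):
        t = brownian_trajectory(rng, 25, 0.5, 0.1)
        u = Trajectory(1, t.frames, t.x, t.y, 0.1)
        tset = TrajectorySet([t, u], frame_time=0.1)
        curve = ensemble_msd(tset, 5)
        for i, n in enumerate(range(1, 6)):
            assert curve.msd[i] == pytest.approx(msd_time_averaged(t, n))

    def test_mobile_plus_stationary_halves(self, rng):
        t = brownian_trajectory(rng, 25, 0.5, 0.1)
        frozen = Trajectory(1, t.frames, np.zeros(len(t)), np.zeros(len(t)), 0.1)
        tset = TrajectorySet([t, frozen], frame_time=0.1)
        curve = ensemble_msd(tset, 4)
        for i, n in enumerate(range(1, 5)):
            assert curve.msd[i] == pytest.approx(0.5 * msd_time_averaged(t, n))

    def test_brownian_matches_4dtau(self, rng):
        D, dt = 0.5, 0.1
        tset = brownian_set(rng, 200, 40, D, dt)
        curve = ensemble_msd(tset, 5)
        per_track = np.array(
            [[msd_time_averaged(t, n) for n in range(1, 6)] for t in tset]
        )
        se = per_track.std(axis=0, ddof=1) / np.sqrt(len(tset))
        np.testing.assert_array_less(np.abs(curve.msd - 4 * D * curve.lags), 3 * se)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            ensemble_msd(TrajectorySet([], frame_time=0.1), 5)

    def test_short_tracks_drop_out_of_long_lags(self):
        long = Trajectory(0, np.arange(10), np.arange(10.0), np.zeros(10), 0.1)
        short = Trajectory(1, np.arange(3), np.arange(3.0), np.zeros(3), 0.1)
        curve = ensemble_msd(TrajectorySet([long, short], frame_time=0.1), 9)
        assert curve.n_obs[0] == 2 and curve.n_obs[-1] == 1
        assert len(curve.lags) == 9


class TestAnomalousFit:
    @pytest.mark.parametrize("D,alpha", [(0.5, 1.0), (0.1, 0.64)])
    def test_noiseless_power_law_recovered_exactly(self, D, alpha):
        lags = np.arange(1, 11) * 0.1
        curve = MSDCurve(lags, 4 * D * lags**alpha, np.full(10, 50))
        fit = fit_anomalous(curve)
        assert fit.D_A == pytest.approx(D, rel=1e-10)
        assert fit.alpha == pytest.approx(alpha, abs=1e-10)

    def test_brownian_simulation_recovery(self, rng):
        tset = brownian_set(rng, 500, 40, 1.0, 0.1)
        fit = fit_anomalous(ensemble_msd(tset, 10))
        assert fit.D_A == pytest.approx(1.0, rel=0.1)
        assert fit.alpha == pytest.approx(1.0, abs=0.1)

    def test_nonpositive_msd_rejected(self):
        curve = MSDCurve([0.1, 0.2], [0.0, 1.0], [5, 5])
        with pytest.raises(ValueError, match="log"):
            fit_anomalous(curve, (0, 2))


class TestTemporalMSD:
    def test_full_window_equals_time_average(self, rng):
        t = brownian_trajectory(rng, 20, 0.3, 0.1)
        for n in (1, 2, 7):
            assert temporal_msd(t, 0, len(t), n) == pytest.approx(
                msd_time_averaged(t, n), rel=1e-12
            )

    def test_hand_evaluation_of_window(self):
        t = Trajectory(0, np.arange(4), [0, 1, 1, 2], [0, 0, 1, 1], 0.1)
        # window of first 3 frames, lag 1: jumps (1,0) and (0,1)
        assert temporal_msd(t, 0, 3, 1) == pytest.approx(1.0)

    def test_constant_trajectory_zero(self):
        t = Trajectory(0, np.arange(10), np.ones(10), np.ones(10), 0.1)
        assert temporal_msd(t, 2, 5, 2) == 0.0

    def test_window_bounds_checked(self, simple_track):
        with pytest.raises(ValueError):
            temporal_msd(simple_track, 1, 3, 1)


class TestTemporalDiffusion:
    def test_printed_weight_reciprocals(self):
        # w(j)^-1 = j (2 j^2 + 1) / (T - j + 1); T = 4
        w = temporal_weights(4)
        un_normalized_inv = np.array([0.75, 6.0, 28.5])
        expected = (1 / un_normalized_inv) / np.sum(1 / un_normalized_inv)
        np.testing.assert_allclose(w, expected, rtol=1e-12)

    def test_weights_sum_to_one(self):
        for T in (2, 4, 16, 64):
            assert temporal_weights(T).sum() == pytest.approx(1.0)

    def test_constant_trajectory_gives_zero(self):
        t = Trajectory(0, np.arange(16), np.ones(16), np.zeros(16), 0.1)
        assert temporal_diffusion(t, 0, 16) == 0.0

    def test_unbiased_on_brownian_windows(self, rng):
        D, dt, T = 0.2, 0.1, 16
        vals = [
            temporal_diffusion(brownian_trajectory(rng, T, D, dt), 0, T)
            for _ in range(4000)
        ]
        assert np.mean(vals) == pytest.approx(D, rel=0.05)


class TestMobilityStates:
    def test_threshold_splits_slow_and_fast(self, rng):
        slow = brownian_trajectory(rng, 40, 0.005, 0.1)
        fast = brownian_trajectory(rng, 40, 0.5, 0.1)
        assert mobility_states(slow).states.all()
        assert not mobility_states(fast).states.any()

    def test_changepoint_located_within_window(self, rng):
        dt, T = 0.1, 16
        steps = rng.normal(0, np.sqrt(2 * 1.0 * dt), size=(49, 2))
        moving = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        frozen = np.tile(moving[-1], (50, 1))
        pos = np.vstack([moving, frozen])
        t = Trajectory(0, np.arange(100), pos[:, 0], pos[:, 1], dt)
        states = mobility_states(t, window=T).states
        switch = np.flatnonzero(states)[0]
        assert abs(int(switch) - 50) <= T

    def test_too_short_trajectory_rejected(self, rng):
        t = brownian_trajectory(rng, 10, 0.1, 0.1)
        with pytest.raises(ValueError):
            mobility_states(t, window=16)


class TestDwellTimes:
    @staticmethod
    def trace(states):
        s = np.array([c == "S" for c in states])
        return MobilityTrace(window=4, d_temp=np.zeros(len(s)), states=s,
                             threshold=0.031)

    def test_interior_run(self):
        d = dwell_times(self.trace("MSSSM"), 0.1)
        assert list(d.durations) == pytest.approx([0.3])
        assert not d.censored[0]

    def test_all_mobile_empty(self):
        assert len(dwell_times(self.trace("MMMM"), 0.1).durations) == 0

    def test_end_touching_runs_censored(self):
        d = dwell_times(self.trace("SSMS"), 0.1)
        assert sorted(d.durations) == pytest.approx([0.1, 0.2])
        assert d.censored.all()


class TestLogNormalFit:
    def test_degenerate_point_mass(self):
        d = DwellSet(np.full(12, np.exp(-8.0)), np.zeros(12, bool))
        fit = fit_lognormal(d)
        assert fit.mu == pytest.approx(-8.0)
        assert fit.sigma == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("sigma", [2.25, 2.55])
    def test_parameter_recovery_at_scale(self, rng, sigma):
        n = 100_000
        d = DwellSet(np.exp(rng.normal(-8.0, sigma, n)), np.zeros(n, bool))
        fit = fit_lognormal(d)
        assert fit.mu == pytest.approx(-8.0, abs=0.02)
        assert fit.sigma == pytest.approx(sigma, abs=0.02)

    def test_censored_dwells_excluded(self, rng):
        good = np.exp(rng.normal(-1.0, 0.5, 50))
        bad = np.full(50, 1e6)
        d = DwellSet(np.concatenate([good, bad]),
                     np.concatenate([np.zeros(50, bool), np.ones(50, bool)]))
        assert fit_lognormal(d).mu == pytest.approx(np.mean(np.log(good)))

    def test_too_few_dwells_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal(DwellSet(np.ones(5), np.zeros(5, bool)))


class TestJumpDistances:
    def test_three_four_five(self):
        t = Trajectory(0, [0, 1], [0.0, 3.0], [0.0, 4.0], 0.1)
        dist = jump_distances(TrajectorySet([t], frame_time=0.1), 1)
        assert list(dist.distances) == pytest.approx([5.0])

    def test_rayleigh_mean_of_localization_noise(self, rng):
        # stationary emitter, per-axis noise sigma_loc: jumps are Rayleigh
        # with scale sigma_loc * sqrt(2); mean = scale * sqrt(pi/2)
        sigma_loc, n = 0.07, 40_000
        pos = rng.normal(0, sigma_loc, size=(n, 2))
        t = Trajectory(0, np.arange(n), pos[:, 0], pos[:, 1], 0.1)
        dist = jump_distances(TrajectorySet([t], frame_time=0.1), 1)
        expected = sigma_loc * np.sqrt(2.0) * np.sqrt(np.pi / 2.0)
        assert np.mean(dist.distances) == pytest.approx(expected, rel=0.02)

    def test_brownian_mean_jump(self, rng):
        D, dt, n_lag = 0.5, 0.1, 4
        tset = brownian_set(rng, 100, 60, D, dt)
        dist = jump_distances(tset, n_lag)
        scale = np.sqrt(2.0 * D * n_lag * dt)
        expected = scale * np.sqrt(np.pi / 2.0)
        se = np.std(dist.distances) / np.sqrt(len(dist.distances) / 8)
        assert abs(np.mean(dist.distances) - expected) < 3 * se

    def test_no_long_enough_track_rejected(self):
        t = Trajectory(0, [0, 1], [0, 1], [0, 0], 0.1)
        with pytest.raises(ValueError):
            jump_distances(TrajectorySet([t], frame_time=0.1), 5)


class TestTwoComponentJumpFit:
    def test_pure_mobile_sample(self, rng):
        tau, D, sloc = 0.1, 0.3, 0.05
        r = rng.rayleigh(np.sqrt(2 * sloc**2 + 2 * D * tau), 5000)
        fit = fit_two_component_jumps(JumpDistanceDistribution(tau, r))
        assert fit["stationary_fraction"] <= 0.05

    def test_pure_stationary_recovers_sigma_loc(self, rng):
        sloc = 0.07
        r = rng.rayleigh(np.sqrt(2) * sloc, 5000)
        fit = fit_two_component_jumps(JumpDistanceDistribution(0.1, r))
        # modal jump of a Rayleigh equals its scale: ~0.1 um here
        assert fit["sigma_loc"] == pytest.approx(sloc, rel=0.1)
        assert np.sqrt(2) * fit["sigma_loc"] == pytest.approx(0.1, rel=0.1)

    def test_fifty_fifty_mixture_recovery(self, rng):
        tau, D, sloc, n = 0.1, 0.3, 0.07, 10_000
        stat = rng.rayleigh(np.sqrt(2) * sloc, n // 2)
        mob = rng.rayleigh(np.sqrt(2 * sloc**2 + 2 * D * tau), n // 2)
        fit = fit_two_component_jumps(
            JumpDistanceDistribution(tau, np.concatenate([stat, mob]))
        )
        assert fit["stationary_fraction"] == pytest.approx(0.5, abs=0.075)
        assert fit["sigma_loc"] == pytest.approx(sloc, rel=0.15)
        assert fit["D_mobile"] == pytest.approx(D, rel=0.15)
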