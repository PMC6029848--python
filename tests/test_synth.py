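import numpy as np
import pytest
import scipy.stats

from openarena.core import SessionConfig, Trajectory
from openarena.preprocess import derive_kinematics
from openarena.synth import (
    CellSpec,
    VRManipulation,
    apply_manipulation,
    make_session,
    make_vr_pair,
    rate_on_trajectory,
    simulate_lfp,
    simulate_spikes,
    simulate_trajectory,
)
from openarena.theta import instantaneous_theta


class TestTrajectory:
    def test_containment_square_and_cylinder(self):
        for shape in ("square", "cylinder"):
            cfg = SessionConfig(trial_duration=120.0, arena_shape=shape, arena_width=60.0)
            tr = simulate_trajectory(cfg, seed=3)
            if shape == "square":
                assert tr.x.min() >= 0 and tr.x.max() <= 60
                assert tr.y.min() >= 0 and tr.y.max() <= 60
            else:
                assert np.hypot(tr.x, tr.y).max() <= 30 + 1e-9

    def test_straight_segments_at_zero_smoothness(self):
        cfg = SessionConfig(trial_duration=60.0)
        tr = derive_kinematics(simulate_trajectory(cfg, smoothness=0.0, seed=1, hd_noise_sd=0.0))
        # between wall bounces the direction is constant: most successive
        # direction changes are ~0
        d = np.diff(tr.run_dir[np.isfinite(tr.run_dir)])
        d = np.abs((d + 180) % 360 - 180)
        assert np.mean(d < 1e-6) > 0.95

    def test_mean_speed_within_ten_percent(self):
        cfg = SessionConfig(trial_duration=2400.0)
        tr = derive_kinematics(simulate_trajectory(cfg, mean_speed=12.0, seed=2))
        assert np.nanmean(tr.speed) == pytest.approx(12.0, rel=0.10)

    def test_deterministic_under_seed(self):
        cfg = SessionConfig(trial_duration=30.0)
        a = simulate_trajectory(cfg, seed=7)
        b = simulate_trajectory(cfg, seed=7)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.hd, b.hd)

    def test_heading_tracks_motion(self):
        cfg = SessionConfig(trial_duration=300.0)
        tr = derive_kinematics(simulate_trajectory(cfg, seed=4, hd_noise_sd=3.0))
        ok = np.isfinite(tr.run_dir)
        d = (tr.hd[ok] - tr.run_dir[ok] + 180) % 360 - 180
        assert np.abs(np.median(d)) < 2.0


class TestSpikes:
    def test_uniform_poisson_count(self, cfg600):
        tr = simulate_trajectory(cfg600, seed=5)
        lam, T = 4.0, cfg600.trial_duration
        st = simulate_spikes(tr, CellSpec(kind="uniform", peak_rate=lam), seed=6)
        assert abs(st.n_spikes - lam * T) < 4 * np.sqrt(lam * T)

    def test_place_spikes_concentrate(self, cfg600):
        tr = simulate_trajectory(cfg600, seed=8)
        spec = CellSpec(
            kind="place", peak_rate=10.0, field_sigma=8.0, field_center=(30.0, 30.0),
            baseline_rate=0.0,
        )
        st = simulate_spikes(tr, spec, seed=9)
        r = np.hypot(st.x - 30, st.y - 30)
        assert np.mean(r <= 3 * 8.0) >= 0.9

    def test_hd_kappa_zero_uniform(self, cfg600):
        tr = simulate_trajectory(cfg600, seed=10)
        st = simulate_spikes(tr, CellSpec(kind="hd", peak_rate=5.0, hd_kappa=0.0), seed=11)
        # chi-square against the occupancy-based expectation
        nb = 12
        occ = np.histogram(tr.hd, bins=nb, range=(0, 360))[0]
        obs = np.histogram(st.hd, bins=nb, range=(0, 360))[0]
        expected = occ / occ.sum() * obs.sum()
        stat = ((obs - expected) ** 2 / expected).sum()
        p = scipy.stats.chi2.sf(stat, nb - 1)
        assert p > 0.01

    def test_time_rescaling_exponential_isis(self, cfg600):
        # Ogata-style check: rescaled ISIs of the thinned train are Exp(1)
        tr = simulate_trajectory(cfg600, seed=12)
        spec = CellSpec(kind="place", peak_rate=8.0, field_sigma=12.0, field_center=(25.0, 35.0))
        st = simulate_spikes(tr, spec, seed=13)
        lam = rate_on_trajectory(spec, tr)
        cum = np.concatenate([[0.0], np.cumsum(lam) * tr.dt])  # Λ at sample edges
        idx = np.clip((st.times / tr.dt).astype(int), 0, tr.n - 1)
        frac = st.times / tr.dt - idx
        big_lambda = cum[idx] + frac * lam[idx] * tr.dt
        u = np.diff(big_lambda)
        p = scipy.stats.kstest(u, "expon").pvalue
        assert p > 0.01

    def test_determinism(self, cfg600):
        tr = simulate_trajectory(cfg600, seed=14)
        spec = CellSpec(kind="grid", peak_rate=10.0, grid_spacing=30.0)
        a = simulate_spikes(tr, spec, seed=15)
        b = simulate_spikes(tr, spec, seed=15)
        np.testing.assert_array_equal(a.times, b.times)


class TestLFP:
    def _const_speed_traj(self, speeds, rate=50.0):
        n = sum(int(s[1] * rate) for s in speeds)
        v = np.concatenate([np.full(int(d * rate), s) for s, d in speeds])
        t = np.arange(n) / rate
        tr = Trajectory(t=t, x=np.zeros(n) + 30, y=np.zeros(n) + 30, hd=np.zeros(n))
        tr.speed = v
        return tr

    def test_pure_sinusoid_flat_frequency(self):
        tr = self._const_speed_traj([(10.0, 60.0)])
        lfp = simulate_lfp(tr, base_freq=8.0, speed_slope=0.0, noise_sd=0.0, seed=0)
        _, freq = instantaneous_theta(lfp)
        mid = freq[500:-500]
        assert np.nanmax(np.abs(mid - 8.0)) < 0.05

    def test_speed_slope_frequency_difference(self):
        # slope 0.1 Hz/(cm/s): freq(v=20) - freq(v=5) = 1.5 Hz
        tr = self._const_speed_traj([(5.0, 120.0), (20.0, 120.0)])
        lfp = simulate_lfp(tr, base_freq=7.5, speed_slope=0.1, noise_sd=0.0, seed=1)
        _, freq = instantaneous_theta(lfp)
        n1 = int(120 * lfp.rate)
        f_lo = np.nanmean(freq[1000 : n1 - 1000])
        f_hi = np.nanmean(freq[n1 + 1000 : -1000])
        assert f_hi - f_lo == pytest.approx(1.5, abs=0.1)

    def test_deterministic(self):
        tr = self._const_speed_traj([(10.0, 10.0)])
        a = simulate_lfp(tr, noise_sd=0.3, seed=5)
        b = simulate_lfp(tr, noise_sd=0.3, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_rate_too_low_raises(self):
        from openarena.core import ValidationError

        tr = self._const_speed_traj([(30.0, 10.0)])
        with pytest.raises(ValidationError):
            simulate_lfp(tr, base_freq=8.0, speed_slope=0.1, lfp_rate=30.0)


class TestVRPair:
    def test_identity_manipulation(self):
        cfg = SessionConfig(trial_duration=60.0)
        spec = CellSpec(kind="place", field_center=(20.0, 40.0), field_sigma=8.0)
        manip = VRManipulation(scale_factor=1.0, grid_scale_factor=1.0)
        out = apply_manipulation(spec, manip, cfg)
        assert out == spec

    def test_rotation_reflects_centers(self):
        cfg = SessionConfig(trial_duration=60.0, arena_width=60.0)
        spec = CellSpec(kind="place", field_center=(20.0, 40.0), hd_mu=30.0)
        out = apply_manipulation(
            spec, VRManipulation(scale_factor=1.0, rotation=180), cfg
        )
        assert out.field_center == (40.0, 20.0)
        assert out.hd_mu == pytest.approx(210.0)

    def test_scale_factor_applied_exactly(self):
        cfg = SessionConfig(trial_duration=60.0)
        place = CellSpec(kind="place", field_sigma=8.0)
        grid = CellSpec(kind="grid", grid_spacing=30.0)
        manip = VRManipulation()  # defaults 1.44 / 1.42
        assert apply_manipulation(place, manip, cfg).field_sigma == pytest.approx(8.0 * 1.44)
        assert apply_manipulation(grid, manip, cfg).grid_spacing == pytest.approx(30.0 * 1.42)

    def test_pair_ground_truth_and_lfp_slope(self):
        cfg = SessionConfig(trial_duration=30.0)
        specs = [CellSpec(kind="place")]
        sr, svr = make_vr_pair(
            specs, VRManipulation(theta_slope_factor=0.5), cfg, cfg, seed=3,
            theta_speed_slope=0.08,
        )
        assert sr.ground_truth["theta_speed_slope"] == pytest.approx(0.08)
        assert svr.ground_truth["theta_speed_slope"] == pytest.approx(0.04)
        assert len(sr.cells) == len(svr.cells) == 1


class TestSessionInvariants:
    def test_spikes_within_trial_and_validates(self, mixed_session):
        mixed_session.validate()
        for c in mixed_session.cells:
            if c.n_spikes:
                assert c.times[0] >= 0
                assert c.times[-1] <= mixed_session.config.trial_duration
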