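import numpy as np
import pytest
import scipy.special

from openarena.core import SessionConfig, SpikeTrain, Trajectory
from openarena.preprocess import derive_kinematics
from openarena.ratemaps import (
    RateMap,
    arena_mask,
    boxcar_smooth,
    detect_fields,
    field_area_fraction,
    make_dir_tuning,
    make_ratemap,
    spatial_autocorr,
)
from openarena.synth import CellSpec, grid_profile, make_session, simulate_spikes


@pytest.fixture(scope="module")
def cfg():
    return SessionConfig(trial_duration=600.0)


def _uniform_scan_traj(cfg, dwell_per_bin=1.0):
    """Deterministic trajectory visiting every bin for dwell_per_bin seconds."""
    n_bins = cfg.n_bins
    per_bin = int(round(dwell_per_bin * cfg.position_rate))
    centers = (np.arange(n_bins) + 0.5) * cfg.bin_size
    xx, yy = np.meshgrid(centers, centers, indexing="ij")
    x = np.repeat(xx.ravel(), per_bin)
    y = np.repeat(yy.ravel(), per_bin)
    t = np.arange(x.size) / cfg.position_rate
    return Trajectory(t=t, x=x, y=y, hd=np.zeros(x.size))


class TestRateMap:
    def test_single_spike_single_bin(self):
        cfg = SessionConfig(trial_duration=1.0)
        n = 50
        tr = Trajectory(
            t=np.arange(n) / 50.0, x=np.full(n, 10.0), y=np.full(n, 10.0), hd=np.zeros(n)
        )
        st = SpikeTrain("c", np.array([0.5])).annotate(tr)
        rm = make_ratemap(tr, st, cfg, smooth_size=0)
        ix = int(10.0 / cfg.bin_size)
        assert rm.rate[ix, ix] == pytest.approx(1.0)
        assert np.nansum(rm.spike_count) == 1

    def test_zero_spikes(self, cfg, mixed_session):
        tr = mixed_session.trajectory
        st = SpikeTrain("empty", np.empty(0)).annotate(tr)
        rm = make_ratemap(tr, st, mixed_session.config)
        assert np.nanmax(rm.rate) == 0.0

    def test_uniform_poisson_rate_recovered(self, mixed_session):
        cell = mixed_session.cell("cell004")  # uniform 3 Hz
        rm = make_ratemap(mixed_session.trajectory, cell, mixed_session.config)
        assert rm.mean_rate == pytest.approx(3.0, rel=0.1)
        # visited-bin average of the smoothed map close to the true rate
        vals = rm.rate[np.isfinite(rm.rate)]
        assert np.median(vals) == pytest.approx(3.0, rel=0.15)

    def test_smoothing_conserves_mass(self, mixed_session):
        cell = mixed_session.cell("cell000")
        rm = make_ratemap(mixed_session.trajectory, cell, mixed_session.config)
        assert rm.spikes_smoothed.sum() == pytest.approx(rm.spike_count.sum(), rel=1e-9)
        assert rm.dwell_smoothed.sum() == pytest.approx(rm.dwell.sum(), rel=1e-9)

    def test_smoothed_peak_not_above_raw_peak(self, mixed_session):
        cell = mixed_session.cell("cell000")
        cfg = mixed_session.config
        raw = make_ratemap(mixed_session.trajectory, cell, cfg, smooth_size=0)
        sm = make_ratemap(mixed_session.trajectory, cell, cfg)
        assert sm.peak_rate <= np.nanmax(raw.rate) + 1e-9

    def test_linear_in_spike_trains(self, mixed_session):
        tr = mixed_session.trajectory
        cfg = mixed_session.config
        a = mixed_session.cell("cell000")
        b = mixed_session.cell("cell004")
        both = SpikeTrain("ab", np.sort(np.concatenate([a.times, b.times]))).annotate(tr)
        rm = make_ratemap(tr, both, cfg)
        ra = make_ratemap(tr, a, cfg)
        rb = make_ratemap(tr, b, cfg)
        np.testing.assert_allclose(rm.spike_count, ra.spike_count + rb.spike_count)


class TestBoxcarSmooth:
    def test_interior_is_plain_average(self):
        mask = np.ones((20, 20), bool)
        rng = np.random.default_rng(0)
        a = rng.uniform(size=(20, 20))
        sm = boxcar_smooth(a, mask, 5)
        import scipy.ndimage as ndi

        plain = ndi.uniform_filter(a, size=5, mode="constant")
        # cells further than one window from the edge see the plain average
        np.testing.assert_allclose(sm[4:-4, 4:-4], plain[4:-4, 4:-4], atol=1e-12)

    def test_conserves_total(self):
        cfg = SessionConfig(arena_shape="cylinder", arena_width=60.0)
        mask = arena_mask(cfg)
        rng = np.random.default_rng(1)
        a = np.where(mask, rng.uniform(size=mask.shape), 0.0)
        assert boxcar_smooth(a, mask, 5).sum() == pytest.approx(a.sum(), rel=1e-12)


class TestDirTuning:
    def test_peak_at_preferred_direction(self, mixed_session):
        cell = mixed_session.cell("cell002")  # hd cell, mu=90
        tun = make_dir_tuning(mixed_session.trajectory, cell)
        peak_dir = tun.centers[np.nanargmax(tun.rate)]
        assert abs((peak_dir - 90 + 180) % 360 - 180) < 15

    def test_constant_rate_flat(self, mixed_session):
        cell = mixed_session.cell("cell004")
        tun = make_dir_tuning(mixed_session.trajectory, cell)
        ok = np.isfinite(tun.rate)
        assert np.nanstd(tun.rate[ok]) / np.nanmean(tun.rate[ok]) < 0.25

    def test_von_mises_rayleigh_matches_bessel_ratio(self):
        # Rayleigh length of a kappa=2 von Mises tuning = I1(2)/I0(2)
        from openarena.metrics import rayleigh_vector

        cfg = SessionConfig(trial_duration=1200.0)
        s = make_session(cfg, [CellSpec(kind="hd", peak_rate=25.0, hd_mu=37.0, hd_kappa=2.0,
                                        baseline_rate=0.0)], seed=55)
        cell = s.cells[0].annotate(s.trajectory)
        tun = make_dir_tuning(s.trajectory, cell)
        expected = scipy.special.iv(1, 2.0) / scipy.special.iv(0, 2.0)
        assert rayleigh_vector(tun) == pytest.approx(expected, rel=0.04)


class TestFields:
    def _map_from_rate(self, rate, bin_size=1.5):
        shape = rate.shape
        ones = np.ones(shape)
        return RateMap(
            rate=rate,
            spike_count=rate.copy(),
            dwell=ones,
            spikes_smoothed=rate.copy(),
            dwell_smoothed=ones,
            bin_size=bin_size,
            mask=np.ones(shape, bool),
        )

    def test_constant_map_area_fraction_one(self):
        rm = self._map_from_rate(np.full((40, 40), 2.0))
        assert field_area_fraction(rm) == 1.0

    def test_gaussian_half_max_area(self):
        # analytic: fraction = pi * 2 ln2 * sigma^2 / N^2 (half-max disc)
        n, sigma = 80, 6.0
        g = np.arange(n)
        xx, yy = np.meshgrid(g, g, indexing="ij")
        rate = 10.0 * np.exp(-((xx - 40) ** 2 + (yy - 40) ** 2) / (2 * sigma**2))
        rm = self._map_from_rate(rate)
        expected = np.pi * 2 * np.log(2) * sigma**2 / n**2
        assert field_area_fraction(rm) == pytest.approx(expected, rel=0.05)

    def test_two_equal_gaussians_give_two_fields(self):
        n = 60
        g = np.arange(n)
        xx, yy = np.meshgrid(g, g, indexing="ij")
        rate = 8.0 * np.exp(-((xx - 15) ** 2 + (yy - 15) ** 2) / 18.0)
        rate += 8.0 * np.exp(-((xx - 45) ** 2 + (yy - 45) ** 2) / 18.0)
        fs = detect_fields(self._map_from_rate(rate))
        assert len(fs) == 2
        areas = sorted(f.area_bins for f in fs.fields)
        assert abs(areas[0] - areas[1]) <= 2
        for f in fs.fields:
            assert f.bins[f.peak_bin]  # every field contains its peak

    def test_fields_disjoint(self, mixed_session):
        cell = mixed_session.cell("cell001")
        rm = make_ratemap(mixed_session.trajectory, cell, mixed_session.config)
        fs = detect_fields(rm)
        total = sum(f.area_bins for f in fs.fields)
        assert (fs.labels >= 0).sum() == total


class TestAutocorr:
    def test_center_is_one_and_symmetric(self, mixed_session):
        cell = mixed_session.cell("cell000")
        rm = make_ratemap(mixed_session.trajectory, cell, mixed_session.config)
        ac = spatial_autocorr(rm)
        cx, cy = ac.center
        assert ac.values[cx, cy] == pytest.approx(1.0, abs=1e-6)
        v = ac.values
        np.testing.assert_allclose(v, v[::-1, ::-1], atol=1e-6, equal_nan=True)

    def test_hex_lattice_peak_distance(self):
        # ideal rate map on a uniform dwell grid: six nearest peaks at the spacing
        cfg = SessionConfig(trial_duration=600.0, arena_width=90.0)
        spacing = 30.0
        n = cfg.n_bins
        centers = (np.arange(n) + 0.5) * cfg.bin_size
        xx, yy = np.meshgrid(centers, centers, indexing="ij")
        rate = 10.0 * grid_profile(xx, yy, spacing, 0.0, (45.0, 45.0))
        ones = np.ones_like(rate)
        rm = RateMap(rate, rate, ones, rate, ones, cfg.bin_size, np.ones_like(rate, bool))
        ac = spatial_autocorr(rm)
        from openarena.metrics import correlogram_peaks, _ring_index

        prof_r = _ring_index(ac.values.shape)
        d = correlogram_peaks(ac.values, min_radius=3.0) * cfg.bin_size
        six = np.sort(d)[:6]
        np.testing.assert_allclose(six, spacing, atol=cfg.bin_size)
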