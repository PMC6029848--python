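import numpy as np
import pytest
import scipy.optimize
import scipy.special

from openarena.core import SessionConfig
from openarena.metrics import (
    directional_information,
    grid_scale,
    gridness,
    map_similarity,
    per_field_dir_info,
    rayleigh_vector,
    skaggs_information,
    spatial_information,
    tuning_similarity,
    tuning_width,
)
from openarena.ratemaps import (
    Correlogram,
    DirectionalTuning,
    RateMap,
    detect_fields,
    make_ratemap,
    spatial_autocorr,
)
from openarena.synth import grid_profile


def _ratemap(rate, dwell=None, bin_size=1.5):
    rate = np.asarray(rate, float)
    dwell = np.ones_like(rate) if dwell is None else np.asarray(dwell, float)
    return RateMap(
        rate=rate,
        spike_count=rate * dwell,
        dwell=dwell,
        spikes_smoothed=rate * dwell,
        dwell_smoothed=dwell,
        bin_size=bin_size,
        mask=np.ones(rate.shape, bool),
    )


def _tuning(rate, occupancy=None, bin_width=6.0):
    rate = np.asarray(rate, float)
    occ = np.ones_like(rate) if occupancy is None else np.asarray(occupancy, float)
    return DirectionalTuning(rate=rate, occupancy=occ, counts=rate * occ, bin_width=bin_width)


def _ideal_grid_correlogram(spacing=30.0, width=90.0, orientation=0.0, bin_size=1.5):
    cfg = SessionConfig(trial_duration=600.0, arena_width=width, bin_size=bin_size)
    n = cfg.n_bins
    c = (np.arange(n) + 0.5) * bin_size
    xx, yy = np.meshgrid(c, c, indexing="ij")
    rate = 10.0 * grid_profile(xx, yy, spacing, orientation, (width / 2, width / 2))
    return spatial_autocorr(_ratemap(rate, bin_size=bin_size))


class TestSkaggsInformation:
    def test_uniform_map_zero(self):
        assert spatial_information(_ratemap(np.full((40, 40), 4.0))) == pytest.approx(0.0, abs=1e-12)

    def test_half_field_double_rate_one_bit(self):
        rate = np.zeros((40, 40))
        rate[:20, :] = 2.0  # half the bins at 2x the mean, uniform dwell
        assert spatial_information(_ratemap(rate)) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(4)
        g = np.arange(30)
        xx, yy = np.meshgrid(g, g, indexing="ij")
        rate = 7.0 * np.exp(-((xx - 12) ** 2 + (yy - 18) ** 2) / 40.0)
        dwell = rng.uniform(0.5, 2.0, rate.shape)
        # independent brute-force implementation
        p = dwell / dwell.sum()
        lam_bar = (p * rate).sum()
        expected = sum(
            p[i, j] * (rate[i, j] / lam_bar) * np.log2(rate[i, j] / lam_bar)
            for i in range(30)
            for j in range(30)
            if rate[i, j] > 0
        )
        assert spatial_information(_ratemap(rate, dwell)) == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        rate = rng.uniform(0, 5, (20, 20))
        a = spatial_information(_ratemap(rate))
        b = spatial_information(_ratemap(rate * 7.3))
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_rate_nan(self):
        assert np.isnan(skaggs_information(np.zeros(10), np.ones(10)))


class TestDirectionalInformation:
    def test_flat_zero(self):
        assert directional_information(_tuning(np.full(60, 3.0))) == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_log2_60(self):
        rate = np.zeros(60)
        rate[17] = 5.0
        assert directional_information(_tuning(rate)) == pytest.approx(np.log2(60), abs=1e-12)

    def test_von_mises_matches_numeric_integration(self):
        kappa, nb = 2.0, 360  # fine bins: discretization error negligible
        th = (np.arange(nb) + 0.5) * (2 * np.pi / nb)
        rate = np.exp(kappa * np.cos(th))
        got = directional_information(_tuning(rate, bin_width=360.0 / nb))
        # oracle: numeric integration of the continuous formula
        lam_bar = rate.mean()
        expected = np.mean(rate / lam_bar * np.log2(rate / lam_bar))
        assert got == pytest.approx(expected, rel=1e-9)


class TestRayleighAndWidth:
    def test_flat_zero_and_single_bin_one(self):
        assert rayleigh_vector(_tuning(np.ones(60))) == pytest.approx(0.0, abs=1e-12)
        one = np.zeros(60)
        one[5] = 4.0
        assert rayleigh_vector(_tuning(one)) == pytest.approx(1.0, abs=1e-12)

    def test_von_mises_bessel_ratio(self):
        th = np.deg2rad((np.arange(360) + 0.5))
        rate = np.exp(2.0 * np.cos(th - 1.0))
        expected = scipy.special.iv(1, 2.0) / scipy.special.iv(0, 2.0)
        assert rayleigh_vector(_tuning(rate, bin_width=1.0)) == pytest.approx(expected, rel=1e-4)

    def test_width_von_mises_kappa1_matches_root(self):
        kappa = 1.0
        th = np.deg2rad(np.arange(0.5, 360, 1.0))
        rate = np.exp(kappa * (np.cos(th) - 1))
        got = tuning_width(_tuning(rate, bin_width=1.0))
        # oracle: half-height crossing of the continuous curve via root finding
        base = np.exp(-2 * kappa)
        half = base + 0.5 * (1 - base)
        f = lambda a: np.exp(kappa * (np.cos(a) - 1)) - half
        root = scipy.optimize.brentq(f, 0, np.pi)
        assert got == pytest.approx(2 * np.rad2deg(root), abs=1.5)

    def test_width_rotation_invariant_and_narrowing(self):
        th = np.deg2rad(np.arange(0.5, 360, 1.0))
        w = []
        for kappa in (1.0, 4.0, 16.0):
            rate = np.exp(kappa * (np.cos(th) - 1))
            w.append(tuning_width(_tuning(rate, bin_width=1.0)))
            rot = tuning_width(_tuning(np.roll(rate, 77), bin_width=1.0))
            assert rot == pytest.approx(w[-1], abs=1e-9)
        assert w[0] > w[1] > w[2]  # width shrinks as kappa grows


class TestGridness:
    def test_ideal_hexagonal_lattice(self):
        ac = _ideal_grid_correlogram(spacing=30.0)
        assert gridness(ac) > 0.8

    def test_square_lattice_negative(self):
        cfg_width, bin_size = 90.0, 1.5
        n = int(cfg_width / bin_size)
        c = (np.arange(n) + 0.5) * bin_size
        xx, yy = np.meshgrid(c, c, indexing="ij")
        k = 2 * np.pi / 30.0
        rate = np.clip(np.cos(k * xx) + np.cos(k * yy), 0, None)
        ac = spatial_autocorr(_ratemap(rate, bin_size=bin_size))
        assert gridness(ac) < 0.0

    def test_single_gaussian_near_zero(self):
        n = 60
        g = np.arange(n)
        xx, yy = np.meshgrid(g, g, indexing="ij")
        rate = 10.0 * np.exp(-((xx - 30) ** 2 + (yy - 30) ** 2) / (2 * 36.0))
        ac = spatial_autocorr(_ratemap(rate))
        assert abs(gridness(ac)) < 0.25

    def test_rotation_by_60_invariant(self):
        g0 = gridness(_ideal_grid_correlogram(orientation=0.0))
        g60 = gridness(_ideal_grid_correlogram(orientation=60.0))
        g17 = gridness(_ideal_grid_correlogram(orientation=17.0))
        assert g0 == pytest.approx(g60, abs=0.05)
        assert g17 > 0.8  # orientation-independent statistic


class TestGridScale:
    def test_recovers_spacing(self):
        ac = _ideal_grid_correlogram(spacing=30.0)
        assert grid_scale(ac) == pytest.approx(30.0, abs=1.5)

    def test_invariant_to_rate_rescaling(self):
        cfg = SessionConfig(trial_duration=600.0, arena_width=90.0)
        n = cfg.n_bins
        c = (np.arange(n) + 0.5) * cfg.bin_size
        xx, yy = np.meshgrid(c, c, indexing="ij")
        rate = 10.0 * grid_profile(xx, yy, 30.0, 0.0, (45.0, 45.0))
        a = grid_scale(spatial_autocorr(_ratemap(rate)))
        b = grid_scale(spatial_autocorr(_ratemap(rate * 5.0)))
        assert a == pytest.approx(b, abs=1e-9)


class TestMapSimilarity:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(3)
        rm = _ratemap(rng.uniform(0, 5, (40, 40)))
        assert map_similarity(rm, rm, 0) == pytest.approx(1.0, abs=1e-12)

    def test_point_reflection_under_180(self):
        rng = np.random.default_rng(4)
        rate = rng.uniform(0, 5, (40, 40))
        rm = _ratemap(rate)
        flipped = _ratemap(rate[::-1, ::-1])
        assert map_similarity(rm, flipped, 180) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = _ratemap(rng.uniform(0, 5, (30, 30)))
        b = _ratemap(rng.uniform(0, 5, (30, 30)))
        assert map_similarity(a, b, 0) == pytest.approx(map_similarity(b, a, 0), abs=1e-12)

    def test_independent_maps_near_zero(self):
        rng = np.random.default_rng(6)
        a = _ratemap(rng.uniform(0, 5, (40, 40)))
        b = _ratemap(rng.uniform(0, 5, (40, 40)))
        assert abs(map_similarity(a, b, 0)) < 3.0 / 40.0  # 3/sqrt(nbins)

    def test_tuning_similarity_rotation(self):
        th = np.deg2rad(np.arange(0.5, 360, 6.0))
        a = _tuning(np.exp(2 * np.cos(th)))
        b = _tuning(np.exp(2 * np.cos(th - np.pi)))
        assert tuning_similarity(a, b, 180) == pytest.approx(1.0, abs=1e-9)
        assert tuning_similarity(a, b, 0) < 0.0


class TestPerFieldDirInfo:
    def test_single_field_matches_whole_cell(self, mixed_session):
        cell = mixed_session.cell("cell000")
        cfg = mixed_session.config
        tr = mixed_session.trajectory
        rm = make_ratemap(tr, cell, cfg)
        fields = detect_fields(rm, min_peak_rate=2.0)
        # the strongest field is the generative one; weak noise bumps may follow
        assert len(fields) >= 1
        assert fields.fields[0].peak_rate == max(f.peak_rate for f in fields.fields)
        res = per_field_dir_info(tr, cell, fields, cfg, pxd=False)
        assert res[0]["n_spikes"] > 50
        assert np.isfinite(res[0]["dir_info"])

    def test_directional_fields_show_more_info_than_pooled(self, cfg600):
        # grid-like cell whose two fields prefer opposite directions
        from openarena.core import SpikeTrain
        from openarena.ratemaps import make_dir_tuning
        from openarena.synth import CellSpec, make_session, simulate_spikes

        specs = [
            CellSpec(kind="place", peak_rate=15.0, field_center=(15.0, 15.0),
                     field_sigma=6.0, dir_mod_depth=0.9, hd_mu=0.0, baseline_rate=0.0),
            CellSpec(kind="place", peak_rate=15.0, field_center=(45.0, 45.0),
                     field_sigma=6.0, dir_mod_depth=0.9, hd_mu=180.0, baseline_rate=0.0),
        ]
        s = make_session(cfg600, specs, seed=77)
        tr = s.trajectory
        merged = SpikeTrain(
            "m", np.sort(np.concatenate([s.cells[0].times, s.cells[1].times]))
        ).annotate(tr)
        rm = make_ratemap(tr, merged, s.config)
        fields = detect_fields(rm, min_peak_rate=2.0)
        res = per_field_dir_info(tr, merged, fields, s.config, pxd=False)
        pooled = directional_information(make_dir_tuning(tr, merged))
        per_field = [r["dir_info"] for r in res if not r["low_count"]]
        assert len(per_field) >= 2
        assert np.mean(per_field) > 3 * pooled
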