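"""Shuffle-based null distributions and spatial-cell classification.

The null for every statistic is the rigid circular time-shift: all spike
times of a cell are offset relative to the trajectory by a single uniform
draw of at least 4 s (wrapping modulo the trial duration), which preserves
the spike train's temporal structure while destroying its relation to
behaviour.  A cell is classified when its observed statistic strictly
exceeds the 99th percentile (linear interpolation between order statistics)
of 1000 such shuffles:

* place cells — spatial information, plus a peak rate above 2 Hz;
* grid cells — gridness, plus a peak rate above 2 Hz;
* head-direction cells — Rayleigh vector length, against the pooled
  population shuffle distribution by default (a per-cell null is available);
* speed cells — Pearson r between running speed and the instantaneous rate
  (spike count per 20 ms position sample / 0.02 s).

The shuffled statistics are computed by a vectorised engine that shares the
shuffled spike→sample assignment across statistics; it reproduces exactly
what the observed-statistic pipeline computes (same binning, smoothing and
metric code paths).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Session, SessionConfig, SpikeTrain, Trajectory, ValidationError
from .metrics import gridness_stack, rayleigh_vector, spatial_information
from .ratemaps import (
    DirectionalTuning,
    arena_mask,
    bin_indices,
    boxcar_smooth,
    circular_boxcar,
    make_dir_tuning,
    make_ratemap,
    masked_autocorr_stack,
    _dir_bin,
)

DEFAULT_N_SHUFFLES = 1000
DEFAULT_MIN_OFFSET = 4.0  # s
PEAK_RATE_THRESHOLD = 2.0  # Hz, auxiliary criterion for place/grid cells
MIN_SPIKES = 100


@dataclass
class ShuffleResult:
    statistic: str
    observed: float
    null_values: np.ndarray
    percentile_99: float
    passes: bool
    aux: dict = field(default_factory=dict)
    low_count: bool = False

    @property
    def n_shuffles(self) -> int:
        return self.null_values.size


# ---------------------------------------------------------------------------
# the shuffle itself
# ---------------------------------------------------------------------------

def draw_offsets(
    rng: np.random.Generator, n: int, duration: float, min_offset: float = DEFAULT_MIN_OFFSET
) -> np.ndarray:
    if duration <= 2 * min_offset:
        raise ValidationError("trial too short for the minimum shuffle offset")
    return rng.uniform(min_offset, duration - min_offset, size=n)


def shuffle_spikes(
    spikes: SpikeTrain,
    traj: Trajectory,
    duration: Optional[float] = None,
    min_offset: float = DEFAULT_MIN_OFFSET,
    seed: int = 0,
    offset: Optional[float] = None,
) -> SpikeTrain:
    """Rigid circular shift of all spike times relative to the trajectory.

    The offset is a single uniform draw from ``[min_offset, T − min_offset]``
    (or the given ``offset``); times wrap modulo the trial duration and the
    annotations are recomputed against the unshifted trajectory.
    """
    T = duration if duration is not None else traj.duration
    if offset is None:
        rng = np.random.default_rng(seed)
        offset = float(draw_offsets(rng, 1, T, min_offset)[0])
    new = np.sort(np.mod(spikes.times + offset, T))
    return SpikeTrain(cell_id=spikes.cell_id, times=new).annotate(traj)


def _shuffled_sample_idx(spikes: SpikeTrain, traj: Trajectory, offsets: np.ndarray) -> np.ndarray:
    """(S, n_spikes) nearest-sample indices of the circularly shifted trains."""
    T = traj.duration
    t = np.mod(spikes.times[None, :] + offsets[:, None], T)
    idx = np.round((t - traj.t[0]) * traj.rate).astype(np.int64)
    return np.clip(idx, 0, traj.n - 1)


# ---------------------------------------------------------------------------
# vectorised null distributions
# ---------------------------------------------------------------------------

def _skaggs_stack(rates: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Skaggs information per row of a (S, B) rate stack (NaN-aware)."""
    w = np.where(np.isfinite(weights) & (weights > 0), weights, 0.0)
    r = np.where(np.isfinite(rates), rates, 0.0)
    used = np.isfinite(rates) & (w > 0)
    wsum = (w * used).sum(axis=1)
    p = np.where(used, w, 0.0) / wsum[:, None]
    lam_bar = (p * r).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = r / lam_bar[:, None]
        term = np.where((r > 0) & used, p * ratio * np.log2(ratio), 0.0)
    out = term.sum(axis=1)
    out[lam_bar <= 0] = np.nan
    return out


def _ratemap_stack(
    traj: Trajectory,
    config: SessionConfig,
    sample_idx: np.ndarray,
    smooth_size: int = 5,
    dtype=np.float64,
):
    """Smoothed rate-map stacks for shuffled spike→sample assignments.

    Returns ``(rate, dwell_s, visited, mask)``: rate (S, n, n) with NaN at
    unvisited bins, exactly as :func:`openarena.ratemaps.make_ratemap` builds
    single maps.
    """
    n = config.n_bins
    mask = arena_mask(config)
    ok = traj.valid
    ix, iy = bin_indices(config, traj.x[ok], traj.y[ok])
    dwell = np.bincount(ix * n + iy, minlength=n * n).reshape(n, n) * traj.dt

    S, nspk = sample_idx.shape
    sx, sy = bin_indices(config, traj.x.take(sample_idx), traj.y.take(sample_idx))
    sb = sx * n + sy
    w = traj.valid.take(sample_idx).astype(float)
    flat = (np.arange(S)[:, None] * (n * n) + sb).ravel()
    spk = np.bincount(flat, weights=w.ravel(), minlength=S * n * n).reshape(S, n, n)

    spk_s = boxcar_smooth(spk, mask, smooth_size).astype(dtype)
    dwell_s = boxcar_smooth(dwell, mask, smooth_size)
    visited = mask & (dwell > 0)
    rate = np.full((S, n, n), np.nan, dtype=dtype)
    div_ok = visited & (dwell_s > 0)
    np.divide(spk_s, np.broadcast_to(dwell_s.astype(dtype), spk_s.shape), out=rate, where=div_ok)
    return rate, dwell_s, visited, mask


def null_spatial_info(
    traj, spikes, config, offsets, smooth_size: int = 5, sample_idx=None
) -> np.ndarray:
    idx = sample_idx if sample_idx is not None else _shuffled_sample_idx(spikes, traj, offsets)
    rate, dwell_s, visited, _ = _ratemap_stack(traj, config, idx, smooth_size)
    S = rate.shape[0]
    return _skaggs_stack(rate.reshape(S, -1), np.broadcast_to(dwell_s.ravel(), (S, dwell_s.size)))


def null_gridness(
    traj, spikes, config, offsets, smooth_size: int = 5, batch: int = 250, sample_idx=None
):
    """Shuffled gridness scores (and shuffled spatial information, which
    shares the rate-map stacks; single-precision stacks keep 1000 shuffled
    40×40 maps and their 79×79 correlograms affordable)."""
    idx = sample_idx if sample_idx is not None else _shuffled_sample_idx(spikes, traj, offsets)
    S = idx.shape[0]
    out = np.empty(S)
    info = np.empty(S)
    for lo in range(0, S, batch):
        sl = slice(lo, min(lo + batch, S))
        rate, dwell_s, visited, _ = _ratemap_stack(
            traj, config, idx[sl], smooth_size, dtype=np.float32
        )
        m = rate.shape[0]
        info[sl] = _skaggs_stack(
            rate.reshape(m, -1).astype(float),
            np.broadcast_to(dwell_s.ravel(), (m, dwell_s.size)),
        )
        ac = masked_autocorr_stack(rate, visited)
        g, _ = gridness_stack(ac)
        out[sl] = g
    return out, info


def null_rayleigh(traj, spikes, config, offsets, smooth_bins: int = 5, sample_idx=None) -> np.ndarray:
    nb = config.n_dir_bins
    ok = traj.valid & np.isfinite(traj.hd)
    occ = np.bincount(_dir_bin(traj.hd[ok], nb), minlength=nb) * traj.dt
    occ_s = circular_boxcar(occ, smooth_bins)

    idx = sample_idx if sample_idx is not None else _shuffled_sample_idx(spikes, traj, offsets)
    hd = traj.hd.take(idx)
    w = (traj.valid.take(idx) & np.isfinite(hd)).astype(float)
    b = _dir_bin(np.where(np.isfinite(hd), hd, 0.0), nb)
    S = idx.shape[0]
    flat = (np.arange(S)[:, None] * nb + b).ravel()
    counts = np.bincount(flat, weights=w.ravel(), minlength=S * nb).reshape(S, nb)
    # circular smoothing of every row (matches circular_boxcar for odd sizes)
    import scipy.ndimage as ndi

    cnt_s = ndi.convolve1d(counts, np.ones(smooth_bins) / smooth_bins, axis=1, mode="wrap")

    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ_s[None, :] > 0, cnt_s / occ_s[None, :], np.nan)
    centers = np.deg2rad((np.arange(nb) + 0.5) * (360.0 / nb))
    r0 = np.where(np.isfinite(rate), rate, 0.0)
    tot = r0.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = np.hypot(r0 @ np.cos(centers), r0 @ np.sin(centers)) / tot
    res[tot <= 0] = np.nan
    return res


def speed_rate_correlation(traj: Trajectory, spikes: SpikeTrain) -> float:
    """Pearson r between running speed and instantaneous rate at 50 Hz samples."""
    v = traj.speed
    if v is None:
        raise ValidationError("speed not derived")
    ok = traj.valid & np.isfinite(v)
    if np.ptp(v[ok]) < 1e-12:
        return np.nan
    counts = np.bincount(spikes.sample_index, minlength=traj.n) if spikes.n_spikes else np.zeros(traj.n)
    rate = counts[ok] / traj.dt
    if np.ptp(rate) < 1e-12:
        return np.nan
    return float(np.corrcoef(v[ok], rate)[0, 1])


def null_speed_r(traj, spikes, offsets, sample_idx: Optional[np.ndarray] = None) -> np.ndarray:
    """Shuffled speed–rate Pearson r, computed from per-shuffle sufficient
    statistics (the per-sample count vector is never materialised)."""
    v = traj.speed
    ok = traj.valid & np.isfinite(v)
    vv = v[ok]
    n_valid = vv.size
    sum_v = float(vv.sum())
    sv2 = float((vv**2).sum())

    idx = sample_idx if sample_idx is not None else _shuffled_sample_idx(spikes, traj, offsets)
    S = idx.shape[0]
    valid_spike = ok.take(idx)
    # Σ c·v per shuffle: sum speed at each (valid) spike's sample
    v_at = np.where(valid_spike, v.take(idx), 0.0)
    sum_cv = v_at.sum(axis=1)
    n_c = valid_spike.sum(axis=1).astype(float)  # Σc
    # Σ c² = Σc + 2·(number of same-sample spike pairs); invalid spikes get
    # unique negative keys so they never pair
    key = np.where(valid_spike, idx, -1 - np.arange(idx.shape[1])[None, :])
    key = np.sort(key, axis=1)
    eq = key[:, 1:] == key[:, :-1]
    col = np.arange(1, idx.shape[1])
    reset = np.where(eq, 0, col)
    last_reset = np.maximum.accumulate(reset, axis=1)
    runpos = np.where(eq, col - last_reset, 0)  # run length so far at each pair
    pairs = runpos.sum(axis=1)
    sum_c2 = n_c + 2.0 * pairs

    num = n_valid * sum_cv - n_c * sum_v
    den_c = np.sqrt(np.clip(n_valid * sum_c2 - n_c**2, 0, None))
    den_v = np.sqrt(n_valid * sv2 - sum_v**2)
    out = np.full(S, np.nan)
    good = (den_c > 1e-12) & (den_v > 1e-12)
    np.divide(num, den_c * den_v, out=out, where=good)
    return out


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def _percentile99(null: np.ndarray) -> float:
    return float(np.nanpercentile(null, 99))


def classify_place(
    session: Session,
    cell: SpikeTrain,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    min_spikes: int = MIN_SPIKES,
) -> ShuffleResult:
    """Place-cell test: spatial information vs its own shuffle null + 2 Hz peak."""
    traj, config = session.trajectory, session.config
    if cell.x is None:
        cell.annotate(traj)
    rm = make_ratemap(traj, cell, config)
    observed = spatial_information(rm)
    rng = np.random.default_rng(seed)
    offsets = draw_offsets(rng, n_shuffles, traj.duration)
    null = null_spatial_info(traj, cell, config, offsets)
    p99 = _percentile99(null)
    low = cell.n_spikes < min_spikes
    passes = (
        not low
        and np.isfinite(observed)
        and observed > p99
        and rm.peak_rate > PEAK_RATE_THRESHOLD
    )
    return ShuffleResult(
        statistic="spatial_information",
        observed=float(observed),
        null_values=null,
        percentile_99=p99,
        passes=bool(passes),
        aux={"peak_rate": rm.peak_rate},
        low_count=low,
    )


def classify_grid(
    session: Session,
    cell: SpikeTrain,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    min_spikes: int = MIN_SPIKES,
) -> ShuffleResult:
    """Grid-cell test: gridness vs its own shuffle null + 2 Hz peak."""
    traj, config = session.trajectory, session.config
    if cell.x is None:
        cell.annotate(traj)
    rm = make_ratemap(traj, cell, config)
    from .metrics import gridness as _gridness
    from .ratemaps import spatial_autocorr

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        observed = _gridness(spatial_autocorr(rm))
    rng = np.random.default_rng(seed)
    offsets = draw_offsets(rng, n_shuffles, traj.duration)
    null, _ = null_gridness(traj, cell, config, offsets)
    p99 = _percentile99(null)
    low = cell.n_spikes < min_spikes
    passes = (
        not low
        and np.isfinite(observed)
        and observed > p99
        and rm.peak_rate > PEAK_RATE_THRESHOLD
    )
    return ShuffleResult(
        statistic="gridness",
        observed=float(observed),
        null_values=null,
        percentile_99=p99,
        passes=bool(passes),
        aux={"peak_rate": rm.peak_rate},
        low_count=low,
    )


def classify_hd(
    session: Session,
    cell: SpikeTrain,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    min_spikes: int = MIN_SPIKES,
    population_null: Optional[np.ndarray] = None,
) -> ShuffleResult:
    """Head-direction test: Rayleigh vector length vs the shuffle null.

    By default the null is this cell's own 1000 shuffles; passing
    ``population_null`` (pooled shuffled Rayleigh values of all cells, see
    :func:`population_hd_null`) applies the common population threshold
    instead.
    """
    traj, config = session.trajectory, session.config
    if cell.x is None:
        cell.annotate(traj)
    tuning = make_dir_tuning(traj, cell, bin_width=config.dir_bin)
    observed = rayleigh_vector(tuning)
    if population_null is None:
        rng = np.random.default_rng(seed)
        offsets = draw_offsets(rng, n_shuffles, traj.duration)
        null = null_rayleigh(traj, cell, config, offsets)
    else:
        null = np.asarray(population_null)
    p99 = _percentile99(null)
    low = cell.n_spikes < min_spikes
    passes = not low and np.isfinite(observed) and observed > p99
    return ShuffleResult(
        statistic="rayleigh_vector",
        observed=float(observed),
        null_values=null,
        percentile_99=p99,
        passes=bool(passes),
        low_count=low,
    )


def population_hd_null(
    session: Session,
    cells: Optional[Sequence[SpikeTrain]] = None,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> np.ndarray:
    """Pooled shuffled Rayleigh values across cells (population shuffling)."""
    traj, config = session.trajectory, session.config
    cells = session.cells if cells is None else cells
    rng = np.random.default_rng(seed)
    pool = []
    for cell in cells:
        if cell.x is None:
            cell.annotate(traj)
        offsets = draw_offsets(rng, n_shuffles, traj.duration)
        pool.append(null_rayleigh(traj, cell, config, offsets))
    return np.concatenate(pool) if pool else np.empty(0)


def classify_speed(
    session: Session,
    cell: SpikeTrain,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    min_spikes: int = MIN_SPIKES,
) -> ShuffleResult:
    """Speed-cell test: speed–rate Pearson r vs its shuffle null."""
    traj = session.trajectory
    if cell.x is None:
        cell.annotate(traj)
    observed = speed_rate_correlation(traj, cell)
    rng = np.random.default_rng(seed)
    offsets = draw_offsets(rng, n_shuffles, traj.duration)
    null = null_speed_r(traj, cell, offsets)
    p99 = _percentile99(null)
    low = cell.n_spikes < min_spikes
    passes = not low and np.isfinite(observed) and observed > p99
    return ShuffleResult(
        statistic="speed_r",
        observed=float(observed),
        null_values=null,
        percentile_99=p99,
        passes=bool(passes),
        low_count=low,
    )


def calibrate_classifiers(
    session: Session,
    cells: Optional[Sequence[SpikeTrain]] = None,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    hd_pooled: bool = True,
):
    """Run all four classifiers on every cell, sharing the shuffle engine.

    One set of shuffle offsets per cell feeds all four statistics, so the
    cost is dominated by a single rate-map/correlogram stack per cell.
    Returns a dict of per-cell arrays (observed statistics, thresholds, pass
    flags).  With ``hd_pooled`` the head-direction threshold is the 99th
    percentile of all cells' shuffled Rayleigh values pooled together.
    """
    import warnings

    from .metrics import gridness as _gridness
    from .ratemaps import spatial_autocorr

    traj, config = session.trajectory, session.config
    cells = session.cells if cells is None else cells
    rng = np.random.default_rng(seed)
    n_cells = len(cells)
    obs = {k: np.full(n_cells, np.nan) for k in ("si", "grid", "ray", "speed", "peak")}
    thr = {k: np.full(n_cells, np.nan) for k in ("si", "grid", "ray", "speed")}
    pval = {k: np.full(n_cells, np.nan) for k in ("si", "grid", "ray", "speed")}
    ray_nulls = []
    for i, cell in enumerate(cells):
        if cell.x is None:
            cell.annotate(traj)
        rm = make_ratemap(traj, cell, config)
        obs["peak"][i] = rm.peak_rate
        obs["si"][i] = spatial_information(rm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs["grid"][i] = _gridness(spatial_autocorr(rm))
        tuning = make_dir_tuning(traj, cell, bin_width=config.dir_bin)
        obs["ray"][i] = rayleigh_vector(tuning)
        obs["speed"][i] = speed_rate_correlation(traj, cell)

        offsets = draw_offsets(rng, n_shuffles, traj.duration)
        idx = _shuffled_sample_idx(cell, traj, offsets)
        g_null, si_null = null_gridness(traj, cell, config, offsets, sample_idx=idx)
        thr["grid"][i] = _percentile99(g_null)
        thr["si"][i] = _percentile99(si_null)
        ray_null = null_rayleigh(traj, cell, config, offsets, sample_idx=idx)
        ray_nulls.append(ray_null)
        thr["ray"][i] = _percentile99(ray_null)
        speed_null = null_speed_r(traj, cell, offsets, sample_idx=idx)
        thr["speed"][i] = _percentile99(speed_null)
        for key, null in (
            ("si", si_null), ("grid", g_null), ("ray", ray_null), ("speed", speed_null)
        ):
            o = {"si": obs["si"], "grid": obs["grid"], "ray": obs["ray"], "speed": obs["speed"]}[key][i]
            if np.isfinite(o):
                pval[key][i] = (1.0 + np.sum(null[np.isfinite(null)] >= o)) / (
                    1.0 + np.sum(np.isfinite(null))
                )

    if hd_pooled:
        pooled = _percentile99(np.concatenate(ray_nulls))
        thr["ray"][:] = pooled
    passes = {
        "place": (obs["si"] > thr["si"]) & (obs["peak"] > PEAK_RATE_THRESHOLD),
        "grid": (obs["grid"] > thr["grid"]) & (obs["peak"] > PEAK_RATE_THRESHOLD),
        "hd": obs["ray"] > thr["ray"],
        "speed": obs["speed"] > thr["speed"],
    }
    return {"observed": obs, "threshold": thr, "passes": passes, "pvalues": pval}


def classify_all(session: Session, n_shuffles: int = DEFAULT_N_SHUFFLES, seed: int = 0):
    """Classification table for every cell in the session (pandas DataFrame)."""
    import pandas as pd

    pop_null = population_hd_null(session, n_shuffles=n_shuffles, seed=seed + 1)
    rows = []
    for i, cell in enumerate(session.cells):
        res = {
            "cell_id": cell.cell_id,
            "n_spikes": cell.n_spikes,
        }
        for name, fn, kw in (
            ("place", classify_place, {}),
            ("grid", classify_grid, {}),
            ("hd", classify_hd, {"population_null": pop_null}),
            ("speed", classify_speed, {}),
        ):
            r = fn(session, cell, n_shuffles=n_shuffles, seed=seed + 100 + i, **kw)
            res[f"{name}_stat"] = r.observed
            res[f"{name}_p99"] = r.percentile_99
            res[f"is_{name}"] = r.passes
        rows.append(res)
    return pd.DataFrame(rows)
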