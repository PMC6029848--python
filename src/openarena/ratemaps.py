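"""Locational and directional firing-rate estimation.

Rate maps follow the standard recipe for open-field tetrode data: positions
are binned into 1.5 × 1.5 cm bins, spike and dwell maps are smoothed
separately with a 5 × 5 boxcar, and the rate map is their ratio.  The boxcar
is truncated at the arena edge and applied in a mass-preserving form (each
bin's content is spread evenly over the in-arena bins of its window), so
smoothing conserves total spike count and total dwell exactly and the rate
estimate stays unbiased at walls, where occupancy is over-represented.

Directional tuning uses 6° bins with a 5-bin circular boxcar; both the bin
width and the smoothing are configurable since they are conventional rather
than principled choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import scipy.fft
import scipy.ndimage as ndi

from .core import SessionConfig, SpikeTrain, Trajectory, ValidationError

MIN_AUTOCORR_OVERLAP = 20  # bins of overlap required per correlogram offset


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def arena_mask(config: SessionConfig) -> np.ndarray:
    """Boolean (nx, ny) mask of bins inside the arena."""
    n = config.n_bins
    if config.arena_shape == "square":
        return np.ones((n, n), dtype=bool)
    c = (np.arange(n) + 0.5) * config.bin_size - config.arena_width / 2.0
    xx, yy = np.meshgrid(c, c, indexing="ij")
    return xx * xx + yy * yy <= (config.arena_width / 2.0) ** 2


def bin_indices(config: SessionConfig, x, y):
    """Map positions (cm) to (ix, iy) bin indices; x first axis."""
    off = 0.0 if config.arena_shape == "square" else config.arena_width / 2.0
    n = config.n_bins
    ix = np.clip(np.floor((np.asarray(x) + off) / config.bin_size).astype(int), 0, n - 1)
    iy = np.clip(np.floor((np.asarray(y) + off) / config.bin_size).astype(int), 0, n - 1)
    return ix, iy


def bin_centers(config: SessionConfig) -> np.ndarray:
    off = 0.0 if config.arena_shape == "square" else -config.arena_width / 2.0
    return (np.arange(config.n_bins) + 0.5) * config.bin_size + off


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _boxsum(a: np.ndarray, size: int) -> np.ndarray:
    """Sum over a size×size window (zero padding), on the last two axes."""
    if a.ndim == 2:
        return ndi.uniform_filter(a, size=size, mode="constant", cval=0.0) * size**2
    return (
        ndi.uniform_filter(a, size=(1, size, size), mode="constant", cval=0.0) * size**2
    )


def boxcar_smooth(a: np.ndarray, mask: np.ndarray, size: int = 5) -> np.ndarray:
    """Mass-preserving truncated boxcar over the in-arena bins.

    Each in-arena bin's content is divided equally among the in-arena bins of
    its size×size window, so column sums of the smoothing operator are one:
    ``smoothed.sum() == a[mask].sum()`` exactly.  Out-of-arena bins are zero.
    """
    cnt = _boxsum(mask.astype(float), size)
    inv = np.zeros_like(cnt)
    np.divide(1.0, cnt, out=inv, where=mask)
    out = _boxsum(a * inv, size)
    return np.where(mask, out, 0.0)


@dataclass
class RateMap:
    """Binned firing-rate surface with its dwell map.

    ``rate`` is smoothed-spikes / smoothed-dwell, NaN at bins never visited
    (raw dwell zero) and outside the arena.  Raw and smoothed maps are kept:
    the raw maps carry the exact counts, the smoothed ones feed the metrics.
    """

    rate: np.ndarray
    spike_count: np.ndarray
    dwell: np.ndarray
    spikes_smoothed: np.ndarray
    dwell_smoothed: np.ndarray
    bin_size: float
    mask: np.ndarray            # in-arena bins
    origin: tuple = (0.0, 0.0)  # cm coordinate of the (0, 0) bin corner

    @property
    def visited(self) -> np.ndarray:
        return self.mask & (self.dwell > 0)

    @property
    def peak_rate(self) -> float:
        r = self.rate[np.isfinite(self.rate)]
        return float(r.max()) if r.size else np.nan

    @property
    def mean_rate(self) -> float:
        """Overall mean rate: total spikes / total dwell."""
        d = self.dwell.sum()
        return float(self.spike_count.sum() / d) if d > 0 else np.nan


def make_ratemap(
    traj: Trajectory,
    spikes: SpikeTrain,
    config: SessionConfig,
    bin_size: Optional[float] = None,
    smooth_size: int = 5,
) -> RateMap:
    """Build a smoothed rate map from a trajectory and an annotated spike train."""
    if traj.n == 0:
        raise ValidationError("empty trajectory")
    cfg = config if bin_size is None else _with_bin_size(config, bin_size)
    n = cfg.n_bins
    mask = arena_mask(cfg)
    dt = traj.dt

    ok = traj.valid
    ix, iy = bin_indices(cfg, traj.x[ok], traj.y[ok])
    dwell = np.bincount(ix * n + iy, minlength=n * n).reshape(n, n) * dt

    if spikes.x is None:
        spikes = spikes.annotate(traj)
    sok = traj.valid[spikes.sample_index] if spikes.n_spikes else np.empty(0, bool)
    sx, sy = bin_indices(cfg, spikes.x[sok], spikes.y[sok])
    spk = np.bincount(sx * n + sy, minlength=n * n).reshape(n, n).astype(float)

    if smooth_size and smooth_size > 1:
        spk_s = boxcar_smooth(spk, mask, smooth_size)
        dwell_s = boxcar_smooth(dwell, mask, smooth_size)
    else:
        spk_s, dwell_s = spk.copy(), dwell.copy()

    rate = np.full((n, n), np.nan)
    visited = mask & (dwell > 0)
    np.divide(spk_s, dwell_s, out=rate, where=visited & (dwell_s > 0))
    return RateMap(
        rate=rate,
        spike_count=spk,
        dwell=dwell,
        spikes_smoothed=spk_s,
        dwell_smoothed=dwell_s,
        bin_size=cfg.bin_size,
        mask=mask,
        origin=(0.0, 0.0)
        if cfg.arena_shape == "square"
        else (-cfg.arena_width / 2.0, -cfg.arena_width / 2.0),
    )


def _with_bin_size(config: SessionConfig, bin_size: float) -> SessionConfig:
    d = config.to_dict()
    d["bin_size"] = bin_size
    return SessionConfig.from_dict(d)


# ---------------------------------------------------------------------------
# directional tuning
# ---------------------------------------------------------------------------

@dataclass
class DirectionalTuning:
    """Firing rate vs head direction."""

    rate: np.ndarray        # Hz per bin, smoothed
    occupancy: np.ndarray   # s per bin, raw
    counts: np.ndarray      # spikes per bin, raw
    bin_width: float        # deg

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.rate.size) + 0.5) * self.bin_width

    @property
    def n_bins(self) -> int:
        return self.rate.size


def circular_boxcar(a: np.ndarray, size: int) -> np.ndarray:
    """Boxcar average with circular (wrap-around) boundary."""
    a = np.asarray(a, dtype=float)
    if size <= 1:
        return a.copy()
    pad = size // 2
    ext = np.concatenate([a[-pad:], a, a[:pad]])
    k = np.ones(size) / size
    return np.convolve(ext, k, mode="valid")[: a.size]


def make_dir_tuning(
    traj: Trajectory,
    spikes: SpikeTrain,
    bin_width: float = 6.0,
    smooth_bins: int = 5,
    angles: str = "hd",
) -> DirectionalTuning:
    """Directional rate: smoothed spike counts / smoothed occupancy per hd bin."""
    nb = int(round(360.0 / bin_width))
    ok = traj.valid
    ang = traj.hd if angles == "hd" else traj.run_dir
    ang = ang[ok]
    ang = ang[np.isfinite(ang)]
    if ang.size == 0:
        raise ValidationError("no valid head-direction samples")
    occ = np.bincount(_dir_bin(ang, nb), minlength=nb) * traj.dt

    if spikes.x is None:
        spikes = spikes.annotate(traj)
    if spikes.n_spikes:
        sok = traj.valid[spikes.sample_index]
        shd = spikes.hd[sok]
        counts = np.bincount(_dir_bin(shd[np.isfinite(shd)], nb), minlength=nb).astype(float)
    else:
        counts = np.zeros(nb)

    occ_s = circular_boxcar(occ, smooth_bins)
    cnt_s = circular_boxcar(counts, smooth_bins)
    rate = np.divide(cnt_s, occ_s, out=np.full(nb, np.nan), where=occ_s > 0)
    return DirectionalTuning(rate=rate, occupancy=occ, counts=counts, bin_width=bin_width)


def _dir_bin(ang, nb):
    return np.clip((np.mod(ang, 360.0) / (360.0 / nb)).astype(int), 0, nb - 1)


# ---------------------------------------------------------------------------
# firing fields
# ---------------------------------------------------------------------------

@dataclass
class Field:
    field_id: int
    bins: np.ndarray          # boolean (nx, ny)
    peak_bin: tuple
    peak_xy: tuple            # cm
    peak_rate: float
    area_bins: int
    area_frac: float          # of in-arena bins


@dataclass
class FieldSet:
    labels: np.ndarray        # int (nx, ny), -1 = background
    fields: List[Field] = field(default_factory=list)

    def __len__(self):
        return len(self.fields)


def field_area_fraction(ratemap: RateMap, threshold_frac: float = 0.5) -> float:
    """Fraction of the arena with rate ≥ ``threshold_frac`` × peak rate."""
    finite = np.isfinite(ratemap.rate)
    if not finite.any():
        raise ValidationError("all-NaN rate map")
    peak = ratemap.rate[finite].max()
    if peak <= 0:
        return 0.0
    above = finite & (ratemap.rate >= threshold_frac * peak)
    return float(above.sum() / ratemap.mask.sum())


def detect_fields(
    ratemap: RateMap,
    threshold_frac: float = 0.5,
    min_peak_rate: float = 1.0,
    min_area_bins: int = 4,
) -> FieldSet:
    """Segment firing fields around local maxima of the smoothed map.

    Local maxima (3×3 neighbourhood) with rate ≥ ``min_peak_rate`` seed
    fields in descending peak order; each field is the connected component of
    bins ≥ ``threshold_frac`` × its own peak, restricted to bins not already
    claimed by a stronger field.
    """
    rate = ratemap.rate
    finite = np.isfinite(rate)
    if not finite.any():
        raise ValidationError("all-NaN rate map")
    r0 = np.where(finite, rate, -np.inf)
    is_max = (ndi.maximum_filter(r0, size=3, mode="constant", cval=-np.inf) == r0) & finite
    is_max &= rate >= min_peak_rate

    labels = np.full(rate.shape, -1, dtype=int)
    fields: List[Field] = []
    order = np.argsort(r0[is_max])[::-1]
    peaks = np.argwhere(is_max)[order]
    unclaimed = finite.copy()
    total_bins = int(ratemap.mask.sum())
    ox, oy = ratemap.origin
    for px, py in peaks:
        if labels[px, py] != -1:
            continue  # sub-peak of an already-claimed field
        thr = threshold_frac * rate[px, py]
        cand = unclaimed & (r0 >= thr)
        lab, _ = ndi.label(cand)
        comp = lab == lab[px, py]
        if comp.sum() < min_area_bins:
            continue
        fid = len(fields)
        labels[comp] = fid
        unclaimed &= ~comp
        peak_xy = (ox + (px + 0.5) * ratemap.bin_size, oy + (py + 0.5) * ratemap.bin_size)
        fields.append(
            Field(
                field_id=fid,
                bins=comp,
                peak_bin=(int(px), int(py)),
                peak_xy=peak_xy,
                peak_rate=float(rate[px, py]),
                area_bins=int(comp.sum()),
                area_frac=float(comp.sum() / total_bins),
            )
        )
    return FieldSet(labels=labels, fields=fields)


# ---------------------------------------------------------------------------
# spatial autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class Correlogram:
    """2-D spatial autocorrelogram (Pearson r per integer-bin offset)."""

    values: np.ndarray  # (2nx-1, 2ny-1), NaN where overlap < minimum
    bin_size: float

    @property
    def center(self) -> tuple:
        return ((self.values.shape[0] - 1) // 2, (self.values.shape[1] - 1) // 2)


def masked_autocorr_stack(
    maps: np.ndarray, mask: np.ndarray, min_overlap: int = MIN_AUTOCORR_OVERLAP
) -> np.ndarray:
    """Pearson autocorrelation at every offset for a stack of maps.

    ``maps`` is (S, nx, ny) with arbitrary values at masked-out bins (they are
    ignored); ``mask`` (nx, ny) marks the bins entering the correlation and is
    shared across the stack.  Returns (S, 2nx-1, 2ny-1); offsets where fewer
    than ``min_overlap`` bin pairs overlap are NaN.
    """
    maps = np.asarray(maps)
    if not np.issubdtype(maps.dtype, np.floating):
        maps = maps.astype(float)
    squeeze = maps.ndim == 2
    if squeeze:
        maps = maps[None]
    S, nx, ny = maps.shape
    px = scipy.fft.next_fast_len(2 * nx - 1)
    py = scipy.fft.next_fast_len(2 * ny - 1)
    m = mask.astype(maps.dtype)
    a = np.where(mask, maps, maps.dtype.type(0))

    fm = scipy.fft.rfft2(m, s=(px, py))
    fa = scipy.fft.rfft2(a, s=(px, py), axes=(1, 2))
    fa2 = scipy.fft.rfft2(a * a, s=(px, py), axes=(1, 2))

    def corr(f1, f2):
        return scipy.fft.irfft2(np.conj(f1) * f2, s=(px, py), axes=(-2, -1))

    # assemble offsets dx ∈ [-(nx-1), nx-1]
    dx = np.arange(-(nx - 1), nx) % px
    dy = np.arange(-(ny - 1), ny) % py

    def take(c):
        return c[..., dx[:, None], dy[None, :]]

    n_ov = take(corr(fm, fm))
    sx = take(corr(fa, fm[None]))
    sxy = take(corr(fa, fa))
    sxx = take(corr(fa2, fm[None]))
    sy = sx[:, ::-1, ::-1]
    syy = sxx[:, ::-1, ::-1]

    n_ov = np.round(n_ov).clip(min=0)
    num = n_ov * sxy - sx * sy
    var1 = n_ov * sxx - sx * sx
    var2 = n_ov * syy - sy * sy
    den = np.sqrt(np.clip(var1, 0, None) * np.clip(var2, 0, None))
    out = np.full(num.shape, np.nan)
    good = (n_ov >= min_overlap) & (den > 1e-12)
    np.divide(num, den, out=out, where=good)
    out = np.clip(out, -1.0, 1.0, out=out)
    return out[0] if squeeze else out


def spatial_autocorr(ratemap: RateMap, min_overlap: int = MIN_AUTOCORR_OVERLAP) -> Correlogram:
    """Spatial autocorrelogram of the smoothed rate map over visited bins."""
    mask = ratemap.visited & np.isfinite(ratemap.rate)
    vals = ratemap.rate
    finite_vals = vals[mask]
    if finite_vals.size == 0:
        raise ValidationError("rate map has no visited bins")
    if np.ptp(finite_vals) < 1e-12:
        import warnings

        warnings.warn("constant rate map: autocorrelogram undefined", stacklevel=2)
        n = vals.shape[0]
        return Correlogram(values=np.full((2 * n - 1, 2 * vals.shape[1] - 1), np.nan), bin_size=ratemap.bin_size)
    ac = masked_autocorr_stack(vals[None], mask, min_overlap)[0]
    return Correlogram(values=ac, bin_size=ratemap.bin_size)
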