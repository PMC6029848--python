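"""Scalar tuning metrics for spatial cells.

Includes the Skaggs information measures (bits/spike), the gridness score and
grid scale from the spatial autocorrelogram, the Rayleigh vector and
half-height tuning width of directional curves, and rate-map similarity for
cue-rotation probes.

Gridness follows the standard construction: an annulus around the
correlogram centre (inner radius where the azimuthal mean of the central
peak first drops below 0.2, outer radius 1.25 × the median distance of the
six nearest peaks) is correlated with itself rotated by 30°–150°, and
gridness is ``min(r60, r120) − max(r30, r90, r150)``.  When the six peaks
cannot be identified the annulus outer radius is swept and the maximum
gridness taken.  All radii and thresholds are keyword-configurable since the
construction is conventional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.ndimage as ndi

from .core import ValidationError
from .ratemaps import Correlogram, DirectionalTuning, RateMap

GRIDNESS_ANGLES = (30, 60, 90, 120, 150)
_ON_PEAK_ANGLES = (60, 120)


# ---------------------------------------------------------------------------
# information measures
# ---------------------------------------------------------------------------

def skaggs_information(rates: np.ndarray, weights: np.ndarray) -> float:
    """Skaggs information, bits/spike: Σ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄)."""
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ok = np.isfinite(rates) & np.isfinite(weights) & (weights > 0)
    rates, weights = rates[ok], weights[ok]
    if rates.size == 0:
        return np.nan
    p = weights / weights.sum()
    lam_bar = float(np.dot(p, rates))
    if lam_bar <= 0:
        return np.nan
    pos = rates > 0
    ratio = rates[pos] / lam_bar
    return float(np.dot(p[pos], ratio * np.log2(ratio)))


def spatial_information(ratemap: RateMap) -> float:
    """Spatial information of the smoothed rate map (dwell-weighted), bits/spike."""
    return skaggs_information(ratemap.rate, ratemap.dwell_smoothed)


def directional_information(tuning: DirectionalTuning) -> float:
    """Directional information of the tuning curve (occupancy-weighted), bits/spike."""
    return skaggs_information(tuning.rate, tuning.occupancy)


# ---------------------------------------------------------------------------
# directional metrics
# ---------------------------------------------------------------------------

def rayleigh_vector(tuning: DirectionalTuning) -> float:
    """Length of the rate-weighted resultant vector, in [0, 1]."""
    ok = np.isfinite(tuning.rate)
    r = tuning.rate[ok]
    if r.size < 2:
        raise ValidationError("need at least two directional bins")
    total = r.sum()
    if total <= 0:
        return np.nan
    ang = np.deg2rad(tuning.centers[ok])
    return float(np.hypot(np.dot(r, np.cos(ang)), np.dot(r, np.sin(ang))) / total)


def tuning_width(tuning: DirectionalTuning) -> float:
    """Angular width (deg) at half height above baseline of the tuning curve.

    Baseline is the curve minimum; the width is the extent of the contiguous
    region around the peak above ``baseline + (peak − baseline) / 2``, with
    linear interpolation at the crossings.
    """
    r = np.asarray(tuning.rate, dtype=float)
    if not np.all(np.isfinite(r)):
        r = np.where(np.isfinite(r), r, np.nanmin(r))
    nb = r.size
    peak = r.max()
    base = r.min()
    if peak - base <= 1e-12:
        return np.nan
    half = base + 0.5 * (peak - base)
    ip = int(np.argmax(r))

    def _walk(direction: int) -> float:
        # bins travelled from the peak until the curve crosses the half level
        for k in range(1, nb):
            j = (ip + direction * k) % nb
            if r[j] < half:
                prev = r[(ip + direction * (k - 1)) % nb]
                frac = (prev - half) / (prev - r[j])
                return (k - 1) + frac
        return nb / 2.0  # never crosses: whole circle above half

    width_bins = _walk(+1) + _walk(-1)
    return float(min(width_bins * tuning.bin_width, 360.0))


# ---------------------------------------------------------------------------
# map similarity (rotation probes)
# ---------------------------------------------------------------------------

def map_similarity(a: RateMap, b: RateMap, rotation: float = 0.0, min_overlap: int = 20) -> float:
    """Pearson correlation between two rate maps, optionally rotating ``b`` 180°."""
    if a.rate.shape != b.rate.shape:
        raise ValidationError("rate maps have different grids")
    if rotation not in (0, 180):
        raise ValidationError("rotation must be 0 or 180 degrees")
    bv = b.rate if rotation == 0 else b.rate[::-1, ::-1]
    ok = np.isfinite(a.rate) & np.isfinite(bv)
    if ok.sum() < min_overlap:
        raise ValidationError(f"fewer than {min_overlap} overlapping bins")
    x, y = a.rate[ok], bv[ok]
    if np.ptp(x) < 1e-12 or np.ptp(y) < 1e-12:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def tuning_similarity(a: DirectionalTuning, b: DirectionalTuning, rotation: float = 0.0) -> float:
    """Pearson correlation between two directional tuning curves after
    rotating ``b`` by ``rotation`` degrees (used for cue-rotation probes on
    head-direction cells, whose spatial rate maps are uninformative)."""
    if a.n_bins != b.n_bins:
        raise ValidationError("tuning curves have different binning")
    shift = int(round(rotation / a.bin_width)) % a.n_bins
    bv = np.roll(b.rate, shift)
    ok = np.isfinite(a.rate) & np.isfinite(bv)
    if ok.sum() < 4:
        return np.nan
    return float(np.corrcoef(a.rate[ok], bv[ok])[0, 1])


# ---------------------------------------------------------------------------
# gridness and grid scale
# ---------------------------------------------------------------------------

_rot_cache: dict = {}


def _rotation_gather(shape, angle_deg):
    """Bilinear resampling indices/weights to rotate an image about its centre."""
    key = (shape, angle_deg)
    if key in _rot_cache:
        return _rot_cache[key]
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    th = np.deg2rad(angle_deg)
    # source coordinates: rotate output grid by -angle about the centre
    sy = cy + (yy - cy) * np.cos(th) + (xx - cx) * np.sin(th)
    sx = cx - (yy - cy) * np.sin(th) + (xx - cx) * np.cos(th)
    y0 = np.floor(sy).astype(int)
    x0 = np.floor(sx).astype(int)
    fy = sy - y0
    fx = sx - x0
    inside = (y0 >= 0) & (y0 < h - 1) & (x0 >= 0) & (x0 < w - 1)
    y0c = np.clip(y0, 0, h - 2)
    x0c = np.clip(x0, 0, w - 2)
    weights = (
        ((1 - fy) * (1 - fx)).astype(np.float32),
        ((1 - fy) * fx).astype(np.float32),
        (fy * (1 - fx)).astype(np.float32),
        (fy * fx).astype(np.float32),
    )
    out = (y0c, x0c, weights, inside)
    _rot_cache[key] = out
    return out


def _rotate_stack(vals: np.ndarray, valid: np.ndarray, angle: float):
    """Rotate a (S,H,W) stack; a rotated pixel is valid iff all 4 sources are."""
    y0, x0, w, inside = _rotation_gather(vals.shape[1:], angle)
    v = np.where(valid, vals, vals.dtype.type(0))
    rot = (
        w[0] * v[:, y0, x0]
        + w[1] * v[:, y0, x0 + 1]
        + w[2] * v[:, y0 + 1, x0]
        + w[3] * v[:, y0 + 1, x0 + 1]
    )
    rval = (
        valid[:, y0, x0]
        & valid[:, y0, x0 + 1]
        & valid[:, y0 + 1, x0]
        & valid[:, y0 + 1, x0 + 1]
        & inside
    )
    return rot, rval


def _masked_pearson_rows(x, y, m):
    """Pearson r per row of (S, P) arrays over boolean mask m (S, P)."""
    n = m.sum(axis=1)
    mx = np.where(m, x, x.dtype.type(0))
    my = np.where(m, y, y.dtype.type(0))
    sx = mx.sum(axis=1)
    sy = my.sum(axis=1)
    sxy = (mx * my).sum(axis=1)
    sxx = (mx * mx).sum(axis=1)
    syy = (my * my).sum(axis=1)
    num = n * sxy - sx * sy
    den = np.sqrt(np.clip(n * sxx - sx * sx, 0, None) * np.clip(n * syy - sy * sy, 0, None))
    out = np.full(n.shape, np.nan)
    good = (n >= 10) & (den > 1e-12)
    np.divide(num, den, out=out, where=good)
    return out


def _ring_index(shape):
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    return np.hypot(yy - cy, xx - cx)


def correlogram_peaks(values: np.ndarray, min_radius: float = 0.0) -> np.ndarray:
    """Distances (bins) from the centre to local maxima beyond ``min_radius``.

    Returns distances sorted ascending; only positive-correlation maxima
    count as candidate grid peaks.
    """
    r = _ring_index(values.shape)
    v = np.where(np.isfinite(values), values, -np.inf)
    is_max = (ndi.maximum_filter(v, size=3, mode="constant", cval=-np.inf) == v) & np.isfinite(
        values
    )
    is_max &= (values > 0) & (r > min_radius)
    return np.sort(r[is_max])


def gridness_stack(
    stack: np.ndarray,
    peak_drop: float = 0.2,
    outer_factor: float = 1.25,
    n_peaks: int = 6,
) -> tuple:
    """Gridness and grid scale (bins) for a stack of correlograms.

    Vectorised across the stack; used both for single maps and for the
    1000-shuffle null distributions.  Returns ``(gridness, scale_bins)``
    arrays of shape (S,).
    """
    stack = np.asarray(stack)
    if not np.issubdtype(stack.dtype, np.floating):
        stack = stack.astype(float)
    S, H, W = stack.shape
    r = _ring_index((H, W))
    rmax = r[0, (W - 1) // 2]  # edge of the inscribed disc
    ring = np.round(r).astype(int)
    nrad = int(ring.max()) + 1
    valid = np.isfinite(stack)
    v0 = np.where(valid, stack, stack.dtype.type(0))

    # azimuthal mean profile per correlogram -> inner radius of the annulus,
    # via one bincount over a combined (s, ring) index
    flat_ring = ring.ravel()
    s_idx = np.repeat(np.arange(S), H * W)
    combined = s_idx * nrad + np.tile(flat_ring, S)
    ring_sum = np.bincount(combined, weights=v0.ravel(), minlength=S * nrad).reshape(S, nrad)
    ring_n = np.bincount(combined, weights=valid.astype(float).ravel(), minlength=S * nrad).reshape(S, nrad)
    with np.errstate(invalid="ignore"):
        prof = ring_sum / ring_n

    below = prof < peak_drop
    below[:, 0] = False
    has_inner = below.any(axis=1)
    inner = np.where(has_inner, np.argmax(below, axis=1), np.nan).astype(float)

    # candidate grid peaks per correlogram
    vmax = ndi.maximum_filter(
        np.where(valid, stack, -np.inf), size=(1, 3, 3), mode="constant", cval=-np.inf
    )
    is_peak = (vmax == v0) & valid & (stack > 0)
    scale = np.full(S, np.nan)
    outer = np.full(S, np.nan)
    for s in range(S):
        if not has_inner[s]:
            continue
        # candidate peaks: beyond the central peak, inside the inscribed disc
        d = r[is_peak[s] & (r > inner[s]) & (r < rmax)]
        if d.size >= 3:
            d = np.sort(d)[:n_peaks]
            scale[s] = np.median(d)
            outer[s] = min(outer_factor * scale[s], rmax)

    gridness = np.full(S, np.nan)
    todo = has_inner & np.isfinite(outer)
    fallback = has_inner & ~np.isfinite(outer)
    if todo.any():
        gridness[todo] = _annulus_gridness(
            stack[todo], valid[todo], r, inner[todo], outer[todo]
        )
    if fallback.any():
        # peaks unclear: sweep the outer radius, take the maximum gridness
        idx = np.flatnonzero(fallback)
        cand = np.linspace(0.35, 0.95, 7) * rmax
        best = np.full(idx.size, np.nan)
        for c in cand:
            ok = c > inner[idx] + 2
            if not ok.any():
                continue
            g = _annulus_gridness(
                stack[idx[ok]], valid[idx[ok]], r, inner[idx[ok]], np.full(ok.sum(), c)
            )
            best[ok] = np.fmax(best[ok], g)
        gridness[idx] = best
    return gridness, scale


def _annulus_gridness(vals, valid, r, inner, outer):
    ann = (r[None] > inner[:, None, None]) & (r[None] <= outer[:, None, None])
    S = vals.shape[0]
    flat = vals.reshape(S, -1)
    vflat = valid.reshape(S, -1)
    annf = ann.reshape(S, -1)
    on, off = [], []
    for angle in GRIDNESS_ANGLES:
        rot, rvalid = _rotate_stack(vals, valid, angle)
        m = annf & vflat & rvalid.reshape(S, -1)
        rr = _masked_pearson_rows(flat, rot.reshape(S, -1), m)
        (on if angle in _ON_PEAK_ANGLES else off).append(rr)
    return np.fmin.reduce(on) - np.fmax.reduce(off)


def gridness(correlogram: Correlogram, **kw) -> float:
    """Gridness score: min correlation at 60°/120° minus max at 30°/90°/150°."""
    g, _ = gridness_stack(correlogram.values[None], **kw)
    if not np.isfinite(g[0]):
        warnings.warn("gridness undefined: no identifiable central peak", stacklevel=2)
    return float(g[0])


def grid_scale(correlogram: Correlogram, **kw) -> float:
    """Grid spacing in cm: median distance of the ≤6 nearest correlogram peaks."""
    _, scale = gridness_stack(correlogram.values[None], **kw)
    return float(scale[0] * correlogram.bin_size)


# ---------------------------------------------------------------------------
# per-field directional information
# ---------------------------------------------------------------------------

def per_field_dir_info(
    traj,
    spikes,
    fields,
    config,
    dir_bin: Optional[float] = None,
    min_spikes: int = 50,
    pxd: bool = True,
):
    """Directional information restricted to each firing field.

    Returns a list of dicts with naive (binned) and, optionally,
    pxd-corrected directional information per field.  Fields with fewer than
    ``min_spikes`` spikes give NaN (flagged ``low_count``).
    """
    from .pxd import fit_pxd, pxd_dir_info
    from .ratemaps import bin_indices, make_dir_tuning

    dir_bin = dir_bin if dir_bin is not None else config.dir_bin
    ix, iy = bin_indices(config, traj.x, traj.y)
    if spikes.x is None:
        spikes = spikes.annotate(traj)
    out = []
    for f in fields.fields:
        in_field = f.bins[ix, iy] & traj.valid
        sub = _restrict_traj(traj, in_field)
        sp_mask = f.bins[
            bin_indices(config, spikes.x, spikes.y)[0],
            bin_indices(config, spikes.x, spikes.y)[1],
        ]
        res = {"field_id": f.field_id, "n_spikes": int(sp_mask.sum()), "low_count": False}
        if sp_mask.sum() < min_spikes:
            warnings.warn(
                f"field {f.field_id}: {int(sp_mask.sum())} spikes < {min_spikes}", stacklevel=2
            )
            res.update(dir_info=np.nan, dir_info_pxd=np.nan, low_count=True)
            out.append(res)
            continue
        sub_spikes = _restrict_spikes(spikes, sp_mask)
        tuning = make_dir_tuning(sub, sub_spikes, bin_width=dir_bin)
        res["dir_info"] = directional_information(tuning)
        if pxd:
            fit = fit_pxd(sub, sub_spikes, config)
            res["dir_info_pxd"] = pxd_dir_info(fit)
        out.append(res)
    return out


def _restrict_traj(traj, keep):
    """Keep the sample grid but invalidate samples outside ``keep``."""
    out = traj.copy()
    out.valid = traj.valid & keep
    return out


def _restrict_spikes(spikes, keep):
    from .core import SpikeTrain

    st = SpikeTrain(cell_id=spikes.cell_id, times=spikes.times[keep])
    st.x = spikes.x[keep]
    st.y = spikes.y[keep]
    st.hd = spikes.hd[keep]
    st.speed = None if spikes.speed is None else spikes.speed[keep]
    st.sample_index = spikes.sample_index[keep]
    return st
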