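"""Two-dimensional theta phase precession.

Each trajectory pass through a firing field is mapped radially onto the unit
disc (the proportional distance between the field peak and the half-max
field edge is preserved), and each spike gets a ``pdcd`` coordinate: its
normalised distance from the field peak projected onto the instantaneous
running direction, ranging from −1 (entering edge) to +1 (exiting edge).
Spike theta phase against pdcd is then fit by circular–linear regression
(slope chosen to maximise the resultant length of the phase residuals,
bounded search), giving the precession slope (deg per pdcd unit), phase
offset, circular–linear correlation and a permutation p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .core import LFPSignal, SessionConfig, SpikeTrain, Trajectory, ValidationError
from .ratemaps import Field, FieldSet, bin_indices
from .theta import phase_at

MIN_PASS_SAMPLES = 3
MIN_FIT_SPIKES = 30
SLOPE_BOUND = 720.0  # deg per pdcd unit, search bound


@dataclass
class Pass:
    """One contiguous in-field trajectory segment, radially normalised."""

    field_id: int
    pass_id: int
    sample_idx: np.ndarray    # indices into the trajectory
    t_start: float
    t_end: float
    norm_x: np.ndarray        # unit-disc coordinates (original orientation)
    norm_y: np.ndarray
    mean_run_dir: float       # deg; rotating by -this zeroes the average direction


@dataclass
class PrecessionSample:
    pdcd: float
    phase: float  # deg
    field_id: int
    pass_id: int


@dataclass
class PrecessionFit:
    slope: float        # deg per pdcd unit
    offset: float       # deg
    circ_lin_r: float
    p: float
    n_spikes: int


# ---------------------------------------------------------------------------
# field geometry
# ---------------------------------------------------------------------------

def _edge_distance(
    f: Field, bin_size: float, origin, angles: np.ndarray, rate: Optional[np.ndarray] = None
) -> np.ndarray:
    """Distance (cm) from the field peak to the field edge along each angle.

    The edge is the half-max contour defining the field.  With the smoothed
    rate map available the contour is located on the bilinearly interpolated
    rate (sub-bin precision, linear interpolation at the crossing); otherwise
    the ray stops at the first bin outside the field mask.
    """
    import scipy.ndimage as ndi

    nx, ny = f.bins.shape
    px, py = f.peak_xy
    step = bin_size / 4.0
    max_steps = int(4 * (nx + ny))
    out = np.empty(angles.size)
    ca, sa = np.cos(np.deg2rad(angles)), np.sin(np.deg2rad(angles))
    half = 0.5 * f.peak_rate
    allowed = ndi.binary_dilation(f.bins, iterations=1)
    r0 = None
    if rate is not None:
        r0 = np.where(np.isfinite(rate), rate, 0.0)
    for k in range(angles.size):
        d = 0.0
        prev_val = f.peak_rate
        for i in range(1, max_steps):
            d = i * step
            gx = px + d * ca[k] - origin[0]
            gy = py + d * sa[k] - origin[1]
            bx = int(gx / bin_size)
            by = int(gy / bin_size)
            if bx < 0 or by < 0 or bx >= nx or by >= ny or not allowed[bx, by]:
                break
            if r0 is not None:
                val = _bilinear(r0, gx / bin_size - 0.5, gy / bin_size - 0.5)
                if val < half:
                    # locate the half-max crossing within the last step
                    t = (prev_val - half) / max(prev_val - val, 1e-12)
                    d = d - step + t * step
                    break
                prev_val = val
            elif not f.bins[bx, by]:
                break
        out[k] = max(d, step)
    return out


def _bilinear(a: np.ndarray, fx: float, fy: float) -> float:
    nx, ny = a.shape
    x0 = min(max(int(np.floor(fx)), 0), nx - 2)
    y0 = min(max(int(np.floor(fy)), 0), ny - 2)
    tx = min(max(fx - x0, 0.0), 1.0)
    ty = min(max(fy - y0, 0.0), 1.0)
    return float(
        a[x0, y0] * (1 - tx) * (1 - ty)
        + a[x0 + 1, y0] * tx * (1 - ty)
        + a[x0, y0 + 1] * (1 - tx) * ty
        + a[x0 + 1, y0 + 1] * tx * ty
    )


def _normalise_positions(f: Field, bin_size: float, origin, x, y, rate=None):
    """Map positions radially to the unit disc, preserving peak→edge fraction."""
    dx = np.asarray(x) - f.peak_xy[0]
    dy = np.asarray(y) - f.peak_xy[1]
    r = np.hypot(dx, dy)
    ang = np.rad2deg(np.arctan2(dy, dx))
    edge = _edge_distance(f, bin_size, origin, ang, rate=rate)
    frac = np.where(r > 0, r / edge, 0.0)
    u = np.deg2rad(ang)
    return frac * np.cos(u), frac * np.sin(u)


# ---------------------------------------------------------------------------
# passes and pdcd
# ---------------------------------------------------------------------------

def extract_passes(
    traj: Trajectory,
    fields: FieldSet,
    config: SessionConfig,
    bin_size: Optional[float] = None,
    min_samples: int = MIN_PASS_SAMPLES,
    rate: Optional[np.ndarray] = None,
) -> List[Pass]:
    """Contiguous in-field trajectory segments, radially normalised per field.

    ``rate`` (the smoothed rate map) refines the field edge to the
    interpolated half-max contour when given.
    """
    bin_size = bin_size if bin_size is not None else config.bin_size
    origin = (0.0, 0.0) if config.arena_shape == "square" else (
        -config.arena_width / 2.0, -config.arena_width / 2.0,
    )
    ix, iy = bin_indices(config, traj.x, traj.y)
    passes: List[Pass] = []
    for f in fields.fields:
        inside = f.bins[ix, iy] & traj.valid
        edges = np.flatnonzero(np.diff(inside.astype(int)))
        starts = edges[inside[edges + 1]] + 1 if edges.size else np.empty(0, int)
        stops = edges[~inside[edges + 1]] + 1 if edges.size else np.empty(0, int)
        if inside[0]:
            starts = np.concatenate([[0], starts])
        if inside[-1]:
            stops = np.concatenate([stops, [traj.n]])
        pid = 0
        for a, b in zip(starts, stops):
            if b - a < min_samples:
                continue
            idx = np.arange(a, b)
            nx_, ny_ = _normalise_positions(
                f, bin_size, origin, traj.x[idx], traj.y[idx], rate=rate
            )
            rd = traj.run_dir[idx] if traj.run_dir is not None else traj.hd[idx]
            rd = rd[np.isfinite(rd)]
            mean_dir = (
                math.degrees(
                    math.atan2(
                        np.sin(np.deg2rad(rd)).mean(), np.cos(np.deg2rad(rd)).mean()
                    )
                )
                % 360.0
                if rd.size
                else 0.0
            )
            passes.append(
                Pass(
                    field_id=f.field_id,
                    pass_id=pid,
                    sample_idx=idx,
                    t_start=float(traj.t[a]),
                    t_end=float(traj.t[b - 1] + traj.dt),
                    norm_x=nx_,
                    norm_y=ny_,
                    mean_run_dir=mean_dir,
                )
            )
            pid += 1
    return passes


def compute_pdcd(
    p: Pass,
    traj: Trajectory,
    spikes: SpikeTrain,
    lfp: LFPSignal,
    phase: Optional[np.ndarray] = None,
) -> List[PrecessionSample]:
    """pdcd and theta phase for every spike inside one pass.

    ``pdcd`` is the spike's normalised position (unit-disc) projected onto
    the unit vector of the instantaneous running direction; spikes at
    stationary samples (undefined direction) are dropped.  ``phase`` may
    carry precomputed per-spike phases to avoid refiltering the LFP.
    """
    sel = np.flatnonzero((spikes.times >= p.t_start) & (spikes.times < p.t_end))
    if sel.size == 0:
        return []
    sidx = traj.nearest_sample(spikes.times[sel])
    pos_in_pass = np.searchsorted(p.sample_idx, np.clip(sidx, p.sample_idx[0], p.sample_idx[-1]))
    pos_in_pass = np.clip(pos_in_pass, 0, p.sample_idx.size - 1)
    rd = traj.run_dir[sidx] if traj.run_dir is not None else traj.hd[sidx]
    keep = np.isfinite(rd)
    if not keep.any():
        return []
    ph = phase[sel] if phase is not None else phase_at(lfp, spikes.times[sel])
    out = []
    ur = np.deg2rad(rd)
    for j in np.flatnonzero(keep):
        k = pos_in_pass[j]
        pd = p.norm_x[k] * math.cos(ur[j]) + p.norm_y[k] * math.sin(ur[j])
        out.append(
            PrecessionSample(
                pdcd=float(pd), phase=float(ph[j]), field_id=p.field_id, pass_id=p.pass_id
            )
        )
    return out


def collect_precession_samples(
    traj: Trajectory,
    spikes: SpikeTrain,
    fields: FieldSet,
    lfp: LFPSignal,
    config: SessionConfig,
    rate: Optional[np.ndarray] = None,
) -> List[PrecessionSample]:
    """All precession samples of one cell across its fields."""
    passes = extract_passes(traj, fields, config, rate=rate)
    phase = phase_at(lfp, spikes.times) if spikes.n_spikes else None
    samples: List[PrecessionSample] = []
    for p in passes:
        samples.extend(compute_pdcd(p, traj, spikes, lfp, phase=phase))
    return samples


# ---------------------------------------------------------------------------
# circular–linear regression
# ---------------------------------------------------------------------------

def _resultant(phases_rad: np.ndarray) -> float:
    return float(np.hypot(np.cos(phases_rad).mean(), np.sin(phases_rad).mean()))


def fit_precession(
    samples: Sequence[PrecessionSample],
    slope_bound: float = SLOPE_BOUND,
    n_perm: int = 500,
    seed: int = 0,
    min_spikes: int = MIN_FIT_SPIKES,
) -> PrecessionFit:
    """Circular–linear regression of spike phase on pdcd.

    The slope maximises the resultant length of the phase residuals
    ``φ − s·x`` over a bounded slope range (dense grid then golden-section
    refinement); the offset is the circular mean of the residuals at the
    optimum.  The correlation is the circular–circular correlation between
    the observed phases and the fitted ones; its p-value comes from
    permuting phases against pdcd.
    """
    x = np.array([s.pdcd for s in samples], dtype=float)
    ph = np.deg2rad([s.phase for s in samples])
    n = x.size
    if n < min_spikes:
        return PrecessionFit(np.nan, np.nan, np.nan, np.nan, n)

    def neg_res(slope_deg):
        return -_resultant(ph - np.deg2rad(slope_deg) * x)

    grid = np.linspace(-slope_bound, slope_bound, 1441)
    vals = [neg_res(s) for s in grid]
    s0 = grid[int(np.argmin(vals))]
    import scipy.optimize

    res = scipy.optimize.minimize_scalar(
        neg_res,
        bounds=(max(-slope_bound, s0 - 5), min(slope_bound, s0 + 5)),
        method="bounded",
    )
    slope = float(res.x)
    resid = ph - np.deg2rad(slope) * x
    offset = math.degrees(math.atan2(np.sin(resid).mean(), np.cos(resid).mean())) % 360.0

    r = _circ_circ_corr(ph, np.deg2rad(slope) * x)
    rng = np.random.default_rng(seed)
    gridp = np.linspace(-slope_bound, slope_bound, 181)
    basis = np.exp(-1j * np.deg2rad(gridp)[:, None] * x[None, :])  # (slopes, n)
    count = 0
    for _ in range(n_perm):
        php = ph[rng.permutation(n)]
        z = basis @ np.exp(1j * php)
        sp = gridp[int(np.argmax(np.abs(z)))]
        rp = _circ_circ_corr(php, np.deg2rad(sp) * x)
        if abs(rp) >= abs(r):
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PrecessionFit(slope=slope, offset=offset, circ_lin_r=float(r), p=float(p), n_spikes=n)


def precession_slope_ci(
    samples: Sequence[PrecessionSample],
    n_boot: int = 200,
    level: float = 0.95,
    slope_bound: float = SLOPE_BOUND,
    seed: int = 0,
) -> tuple:
    """Bootstrap confidence interval for the precession slope.

    Resamples (pdcd, phase) pairs with replacement; each replicate's slope is
    the resultant-maximising slope on a 2°-resolution grid (the bootstrap is
    vectorised through multinomial weights, so the basis matrix is built
    once).
    """
    x = np.array([s.pdcd for s in samples], dtype=float)
    ph = np.deg2rad([s.phase for s in samples])
    n = x.size
    rng = np.random.default_rng(seed)
    grid = np.linspace(-slope_bound, slope_bound, int(slope_bound * 2 / 2) + 1)
    basis = np.exp(-1j * np.deg2rad(grid)[:, None] * x[None, :])
    w = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).T  # (n, n_boot)
    z = basis @ (w * np.exp(1j * ph)[:, None])                  # (slopes, n_boot)
    slopes = grid[np.argmax(np.abs(z), axis=0)]
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(slopes, alpha)),
        float(np.quantile(slopes, 1.0 - alpha)),
    )


def _circ_circ_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Circular–circular correlation (Fisher–Lee) between two angle arrays."""
    abar = math.atan2(np.sin(a).mean(), np.cos(a).mean())
    bbar = math.atan2(np.sin(b).mean(), np.cos(b).mean())
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    denom = math.sqrt((sa**2).sum() * (sb**2).sum())
    if denom < 1e-12:
        return 0.0
    return float((sa * sb).sum() / denom)
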