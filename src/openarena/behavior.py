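"""Behavioural summary statistics of open-arena foraging.

These metrics operate on the 2.5 Hz down-sampled, boxcar-smoothed trajectory
(see :func:`openarena.preprocess.downsample_behavior`): the Rayleigh vector
of running direction, the mean absolute change of running direction between
samples (path straightness), the path excess ratio between two goal
locations, quadrant dwell fractions, and a wall-following index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SessionConfig, Trajectory, ValidationError, wrap_diff_deg


@dataclass
class BehaviorSummary:
    mean_speed: float               # cm/s
    dir_rayleigh: float             # [0, 1]
    mean_abs_dir_change: float      # deg / sample
    quadrant_fraction: np.ndarray   # 4 fractions summing to 1
    wall_follow_fraction: float     # fraction of samples running wall-parallel


def running_dir_rayleigh(traj: Trajectory) -> float:
    """Resultant length of unit vectors along running direction, [0, 1]."""
    rd = traj.run_dir
    if rd is None:
        raise ValidationError("run_dir not derived; call derive_kinematics first")
    ok = traj.valid & np.isfinite(rd)
    if ok.sum() < 2:
        raise ValidationError("need at least two valid running-direction samples")
    ang = np.deg2rad(rd[ok])
    return float(np.hypot(np.cos(ang).mean(), np.sin(ang).mean()))


def mean_abs_direction_change(traj: Trajectory) -> float:
    """Mean |Δ running direction| between consecutive samples, deg/sample."""
    rd = traj.run_dir
    if rd is None:
        raise ValidationError("run_dir not derived; call derive_kinematics first")
    ok = traj.valid & np.isfinite(rd)
    pair = ok[:-1] & ok[1:]
    if not pair.any():
        return np.nan
    d = wrap_diff_deg(rd[1:][pair] - rd[:-1][pair])
    return float(np.abs(d).mean())


def path_excess_ratio(
    traj: Trajectory, start, goal, t0: float, t1: float
) -> float:
    """Actual path length over [t0, t1] divided by the start–goal distance."""
    start = np.asarray(start, dtype=float)
    goal = np.asarray(goal, dtype=float)
    if t0 >= t1:
        raise ValidationError("t0 must precede t1")
    sep = float(np.hypot(*(goal - start)))
    if sep <= 0:
        raise ValidationError("start and goal coincide")
    sel = (traj.t >= t0) & (traj.t <= t1) & traj.valid
    x, y = traj.x[sel], traj.y[sel]
    if x.size < 2:
        raise ValidationError("no trajectory samples in [t0, t1]")
    path = float(np.hypot(np.diff(x), np.diff(y)).sum())
    return path / sep


def quadrant_dwell(
    traj: Trajectory, config: SessionConfig, intervals=None
) -> np.ndarray:
    """Fraction of valid samples in each arena quadrant.

    Quadrant order: (low-x, low-y), (high-x, low-y), (low-x, high-y),
    (high-x, high-y).  Samples exactly on a dividing line go to the
    lower-index quadrant (half-open convention).  ``intervals`` optionally
    restricts to a list of (t_start, t_end) windows, e.g. the runs between
    specific rewards.
    """
    if config.arena_shape != "square":
        raise ValidationError("quadrant analysis requires a square arena")
    sel = traj.valid.copy()
    if intervals is not None:
        in_any = np.zeros(traj.n, dtype=bool)
        for a, b in intervals:
            in_any |= (traj.t >= a) & (traj.t <= b)
        sel &= in_any
    if not sel.any():
        raise ValidationError("no samples selected")
    half = config.arena_width / 2.0
    qx = (traj.x[sel] >= half).astype(int)
    qy = (traj.y[sel] >= half).astype(int)
    counts = np.bincount(qx + 2 * qy, minlength=4)
    return counts / counts.sum()


def wall_follow_fraction(
    traj: Trajectory, config: SessionConfig, tol_deg: float = 15.0
) -> float:
    """Fraction of samples whose running direction is within ``tol_deg`` of a
    wall axis (square arenas: 0° or 90°; cylinders: the local tangent).

    A pragmatic summary of wall-following tendency; the exact statistic used
    for this behaviour varies between labs.
    """
    rd = traj.run_dir
    ok = traj.valid & np.isfinite(rd)
    if not ok.any():
        return np.nan
    if config.arena_shape == "square":
        d = np.minimum.reduce([np.abs(wrap_diff_deg(rd[ok] - a)) for a in (0, 90, 180, 270)])
    else:
        tangent = np.rad2deg(np.arctan2(traj.y[ok], traj.x[ok])) + 90.0
        d = np.abs(wrap_diff_deg(rd[ok] - tangent))
        d = np.minimum(d, 180.0 - d)
    return float((d <= tol_deg).mean())


def summarize_behavior(traj: Trajectory, config: SessionConfig) -> BehaviorSummary:
    """All behavioural metrics on an already down-sampled trajectory."""
    ok = traj.valid & np.isfinite(traj.speed if traj.speed is not None else np.nan * traj.t)
    mean_speed = float(traj.speed[ok].mean()) if ok.any() else np.nan
    return BehaviorSummary(
        mean_speed=mean_speed,
        dir_rayleigh=running_dir_rayleigh(traj),
        mean_abs_dir_change=mean_abs_direction_change(traj),
        quadrant_fraction=quadrant_dwell(traj, config)
        if config.arena_shape == "square"
        else np.full(4, np.nan),
        wall_follow_fraction=wall_follow_fraction(traj, config),
    )
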