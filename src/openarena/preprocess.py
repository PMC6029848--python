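"""Position cleaning and kinematics.

Tracking at 50 Hz occasionally drops samples (cable occlusion of the head
LEDs).  The cleaning pipeline mirrors standard practice for this kind of
data: short gaps are filled by linear interpolation per channel, positions
are then smoothed with a 400 ms boxcar, and speed / running direction are
derived from the smoothed displacements.  Head direction (``hd``, from the
LED pair or the synthetic heading) is kept distinct from running direction
(``run_dir``, from displacement): directional tuning of cells uses ``hd``,
behavioural directionality uses ``run_dir``.
"""

from __future__ import annotations

import numpy as np

from .core import Trajectory, ValidationError, wrap_deg

DEFAULT_MAX_GAP = 0.5  # s; longer tracking losses stay masked


def interpolate_gaps(traj: Trajectory, max_gap: float = DEFAULT_MAX_GAP) -> Trajectory:
    """Fill tracking gaps up to ``max_gap`` seconds by linear interpolation.

    Each channel (x, y, and head direction, the latter via its unwrapped
    angle) is interpolated separately between the nearest valid samples.
    Gaps longer than ``max_gap`` remain masked and are excluded downstream.
    """
    out = traj.copy()
    valid = out.valid
    if not valid.any():
        raise ValidationError("cannot interpolate: no valid samples")
    if valid.all():
        return out

    n = out.n
    idx = np.arange(n)
    gap_id = np.cumsum(np.diff(np.concatenate([[True], valid]).astype(int)) == -1)
    max_len = int(round(max_gap * out.rate))

    fillable = np.zeros(n, dtype=bool)
    invalid_idx = idx[~valid]
    for g in np.unique(gap_id[~valid]):
        members = invalid_idx[gap_id[~valid] == g]
        lo, hi = members[0] - 1, members[-1] + 1
        if lo < 0 or hi >= n:
            continue  # gap touches a trial edge: no anchor on one side
        if members.size <= max_len:
            fillable[members] = True

    vi = idx[valid]
    for name in ("x", "y"):
        ch = getattr(out, name)
        ch[fillable] = np.interp(idx[fillable], vi, ch[valid])
    hd_unwrapped = np.full(n, np.nan)
    hd_unwrapped[valid] = np.unwrap(np.deg2rad(out.hd[valid]))
    out.hd[fillable] = wrap_deg(
        np.rad2deg(np.interp(idx[fillable], vi, hd_unwrapped[valid]))
    )
    out.valid = valid | fillable
    return out


def smooth_positions(traj: Trajectory, window: float = 0.4) -> Trajectory:
    """Boxcar-smooth x and y independently (default 400 ms window).

    The window is truncated at trial edges and around masked samples and
    renormalised over the valid samples it covers, so the output at every
    valid sample is the plain average of the valid samples in its window
    (it never leaves their convex hull).
    """
    out = traj.copy()
    w = int(round(window * out.rate))
    if w < 1:
        raise ValidationError("smoothing window shorter than one sample period")
    if w == 1:
        return out
    if w % 2 == 0:
        # symmetric variant of the even-length boxcar: half-weight end taps
        # (keeps the window centred so linear trends pass through unchanged)
        kernel = np.concatenate([[0.5], np.ones(w - 1), [0.5]])
    else:
        kernel = np.ones(w)
    vm = out.valid.astype(float)
    norm = np.convolve(vm, kernel, mode="same")
    for name in ("x", "y"):
        ch = getattr(out, name)
        num = np.convolve(np.where(out.valid, ch, 0.0), kernel, mode="same")
        smoothed = np.divide(num, norm, out=np.full_like(num, np.nan), where=norm > 0)
        ch[out.valid] = smoothed[out.valid]
    return out


def derive_kinematics(traj: Trajectory) -> Trajectory:
    """Derive speed (cm/s) and running direction (deg) from displacements.

    Forward differences: sample ``i`` carries the displacement from ``i`` to
    ``i+1`` (the last sample repeats its predecessor).  Samples adjacent to a
    masked endpoint get NaN speed; ``run_dir`` is additionally NaN where the
    displacement is zero (running direction undefined when stationary).
    """
    out = traj.copy()
    n = out.n
    dt = out.dt
    dx = np.diff(out.x)
    dy = np.diff(out.y)
    pair_ok = out.valid[:-1] & out.valid[1:]

    speed = np.full(n, np.nan)
    run_dir = np.full(n, np.nan)
    step = np.hypot(dx, dy)
    speed[:-1] = np.where(pair_ok, step / dt, np.nan)
    moving = pair_ok & (step > 0)
    run_dir[:-1] = np.where(
        moving, wrap_deg(np.rad2deg(np.arctan2(dy, dx))), np.nan
    )
    if n >= 2:
        speed[-1] = speed[-2]
        run_dir[-1] = run_dir[-2]
    out.speed = speed
    out.run_dir = run_dir
    return out


def downsample_behavior(traj: Trajectory, rate: float = 2.5) -> Trajectory:
    """Keep every k-th sample for behavioural metrics (default 50 → 2.5 Hz)."""
    step_f = traj.rate / rate
    step = int(round(step_f))
    if step < 1 or abs(step_f - step) > 1e-6:
        raise ValidationError(
            f"target rate {rate} Hz does not divide the position rate {traj.rate:.6g} Hz"
        )
    sl = slice(None, None, step)
    return Trajectory(
        t=traj.t[sl],
        x=traj.x[sl],
        y=traj.y[sl],
        hd=traj.hd[sl],
        speed=None if traj.speed is None else traj.speed[sl],
        run_dir=None if traj.run_dir is None else traj.run_dir[sl],
        valid=traj.valid[sl],
    )


def preprocess(traj: Trajectory, max_gap: float = DEFAULT_MAX_GAP, window: float = 0.4) -> Trajectory:
    """Full cleaning chain: interpolate gaps, smooth, derive kinematics."""
    if not traj.valid.all():
        traj = interpolate_gaps(traj, max_gap=max_gap)
    traj = smooth_positions(traj, window=window)
    # re-derive run_dir/speed on the smoothed path
    return derive_kinematics(traj)
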