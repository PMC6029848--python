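"""Synthetic open-arena sessions.

No raw recordings accompany the analyses this package implements, so every
stage is validated against simulated sessions whose generative parameters
are known.  The generator emulates the statistical structure the analyses
assume:

* random-foraging trajectories (mean-reverting speed, small heading noise,
  specular wall reflection) sampled at 50 Hz,
* inhomogeneous-Poisson spike trains for place, grid, head-direction,
  speed-modulated and uniform cells (thinning at the trajectory rate),
* a speed-coupled theta LFP (phase-continuous oscillation whose
  instantaneous frequency is ``base + slope · v(t)``),
* virtual-reality manipulations: linear field/grid expansion (defaults 1.44
  and 1.42, the expansion factors the analyses are expected to recover),
  added place-cell directionality, a reduced theta–speed slope and a 180°
  cue rotation.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    LFPSignal,
    Session,
    SessionConfig,
    SpikeTrain,
    Trajectory,
    ValidationError,
    wrap_deg,
    wrap_diff_deg,
)

DEFAULT_MEAN_SPEED = 12.0  # cm/s, typical trained-mouse foraging speed
DEFAULT_THETA_FREQ = 8.0   # Hz
DEFAULT_THETA_SLOPE = 0.08  # Hz per cm/s


@dataclass
class CellSpec:
    """Generative parameters of one simulated cell."""

    kind: str = "place"  # place | grid | hd | speed | uniform
    peak_rate: float = 8.0
    field_center: Tuple[float, float] = (30.0, 30.0)
    field_sigma: float = 8.0       # cm, Gaussian place field
    grid_spacing: float = 30.0     # cm
    grid_orientation: float = 0.0  # deg
    hd_mu: float = 0.0             # deg; also the preferred direction of dir_mod
    hd_kappa: float = 4.0
    speed_slope: float = 0.2       # Hz per cm/s
    dir_mod_depth: float = 0.0     # multiplicative directional modulation, [0, 1]
    precession_range: float = 0.0  # deg of phase swept across a field (0 = off)
    baseline_rate: float = 0.1     # Hz

    def __post_init__(self) -> None:
        if self.kind not in ("place", "grid", "hd", "speed", "uniform"):
            raise ValidationError(f"unknown cell kind {self.kind!r}")
        if self.peak_rate < 0 or self.baseline_rate < 0:
            raise ValidationError("rates must be non-negative")
        if self.hd_kappa < 0:
            raise ValidationError("hd_kappa must be non-negative")
        if not 0 <= self.dir_mod_depth <= 1:
            raise ValidationError("dir_mod_depth must lie in [0, 1]")


@dataclass
class VRManipulation:
    """How a VR session differs from its paired real session.

    ``scale_factor`` expands place-field sigma linearly (1.44, the measured
    field expansion); ``grid_scale_factor`` expands grid spacing (1.42).
    ``added_dir_mod`` adds directional modulation to place cells only;
    ``theta_slope_factor`` multiplies the LFP theta–speed slope; ``rotation``
    (0 or 180°) rotates all spatial tuning about the arena centre.
    """

    scale_factor: float = 1.44
    grid_scale_factor: float = 1.42
    added_dir_mod: float = 0.0
    theta_slope_factor: float = 1.0
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0 or self.grid_scale_factor <= 0:
            raise ValidationError("scale factors must be positive")
        if self.rotation not in (0, 180):
            raise ValidationError("rotation must be 0 or 180 degrees")
        if not 0 < self.theta_slope_factor <= 1:
            raise ValidationError("theta_slope_factor must lie in (0, 1]")


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def simulate_trajectory(
    config: SessionConfig,
    mean_speed: float = DEFAULT_MEAN_SPEED,
    smoothness: float = 1.0,
    wall_follow_bias: float = 0.0,
    seed: int = 0,
    hd_noise_sd: float = 3.0,
) -> Trajectory:
    """Random-foraging trajectory at the configured position rate.

    Speed follows a mean-reverting (OU) process around ``mean_speed`` and the
    heading a small-step random walk; both noise scales are proportional to
    ``smoothness`` (0 gives straight constant-speed segments with specular
    wall reflection).  ``wall_follow_bias`` in [0, 1] steers the heading
    toward the nearest wall-parallel direction near walls, emulating
    thigmotaxis.  Head direction equals the direction of motion plus a small
    wrapped-normal error (the head is free only to rotate horizontally).
    """
    rng = np.random.default_rng(seed)
    if not 0 <= wall_follow_bias <= 1:
        import warnings

        warnings.warn("wall_follow_bias clamped to [0, 1]", stacklevel=2)
        wall_follow_bias = min(max(wall_follow_bias, 0.0), 1.0)

    n = int(round(config.trial_duration * config.position_rate))
    dt = 1.0 / config.position_rate
    w = config.arena_width
    square = config.arena_shape == "square"
    lo, hi = (0.0, w) if square else (-w / 2.0, w / 2.0)
    radius = w / 2.0

    tau_s = 1.0                      # s, speed relaxation time
    sigma_s = 0.4 * mean_speed * smoothness  # stationary speed sd ≈ 0.28·mean
    sigma_psi = 1.6 * smoothness     # rad / sqrt(s), heading diffusion

    x = np.empty(n)
    y = np.empty(n)
    psi = np.empty(n)  # motion heading, rad
    if square:
        x0, y0 = rng.uniform(0.1 * w, 0.9 * w, size=2)
    else:
        r0 = radius * 0.7 * math.sqrt(rng.uniform())
        a0 = rng.uniform(0, 2 * math.pi)
        x0, y0 = r0 * math.cos(a0), r0 * math.sin(a0)
    x[0], y[0] = x0, y0
    psi_c = rng.uniform(0, 2 * math.pi)
    s_c = mean_speed

    margin = 0.15 * w
    noise_s = sigma_s * math.sqrt(2 * dt / tau_s) * rng.standard_normal(n)
    noise_psi = sigma_psi * math.sqrt(dt) * rng.standard_normal(n)
    for i in range(n):
        psi[i] = psi_c
        if i == n - 1:
            break
        # speed: OU, reflected at zero
        s_c += (mean_speed - s_c) * dt / tau_s + noise_s[i]
        s_c = abs(s_c)
        # heading random walk (+ optional wall-following torque)
        psi_c += noise_psi[i]
        if wall_follow_bias > 0:
            torque = _wall_torque(x[i], y[i], psi_c, lo, hi, radius, square, margin)
            psi_c += wall_follow_bias * torque * dt
        nx = x[i] + s_c * dt * math.cos(psi_c)
        ny = y[i] + s_c * dt * math.sin(psi_c)
        # specular reflection at the boundary
        for _ in range(4):
            if square:
                bounced = False
                if nx < lo:
                    nx = 2 * lo - nx
                    psi_c = math.pi - psi_c
                    bounced = True
                elif nx > hi:
                    nx = 2 * hi - nx
                    psi_c = math.pi - psi_c
                    bounced = True
                if ny < lo:
                    ny = 2 * lo - ny
                    psi_c = -psi_c
                    bounced = True
                elif ny > hi:
                    ny = 2 * hi - ny
                    psi_c = -psi_c
                    bounced = True
                if not bounced:
                    break
            else:
                rr = math.hypot(nx, ny)
                if rr <= radius:
                    break
                # reflect about the tangent at the crossing point
                ux, uy = nx / rr, ny / rr
                vx, vy = math.cos(psi_c), math.sin(psi_c)
                dot = vx * ux + vy * uy
                vx, vy = vx - 2 * dot * ux, vy - 2 * dot * uy
                psi_c = math.atan2(vy, vx)
                nx, ny = (2 * radius - rr) * ux, (2 * radius - rr) * uy
        if square:
            nx = min(max(nx, lo), hi)
            ny = min(max(ny, lo), hi)
        else:
            rr = math.hypot(nx, ny)
            if rr > radius:
                nx, ny = nx * radius / rr, ny * radius / rr
        x[i + 1], y[i + 1] = nx, ny

    hd = wrap_deg(np.rad2deg(psi) + hd_noise_sd * rng.standard_normal(n))
    t = np.arange(n) * dt
    return Trajectory(t=t, x=x, y=y, hd=hd)


def _wall_torque(x, y, psi, lo, hi, radius, square, margin):
    """Torque (rad/s) steering the heading parallel to the nearest wall."""
    if square:
        dists = (x - lo, hi - x, y - lo, hi - y)
        dmin = min(dists)
        if dmin > margin:
            return 0.0
        k = dists.index(dmin)
        wall_axis = 90.0 if k < 2 else 0.0  # run parallel to the near wall
    else:
        rr = math.hypot(x, y)
        if radius - rr > margin:
            return 0.0
        wall_axis = math.degrees(math.atan2(y, x)) + 90.0
    cur = math.degrees(psi)
    # steer toward whichever sense of the wall axis is closer
    d1 = float(wrap_diff_deg(wall_axis - cur))
    d2 = float(wrap_diff_deg(wall_axis + 180.0 - cur))
    d = d1 if abs(d1) < abs(d2) else d2
    return math.radians(d) * 2.0


def biased_crossing_trajectory(
    config: SessionConfig,
    sequence: Sequence[str] = ("E", "E", "E", "W", "N", "S"),
    speed: float = 12.0,
    margin: float = 2.0,
) -> Trajectory:
    """Deterministic loops crossing the arena centre in a biased direction mix.

    Each loop crosses the middle of a square arena in one cardinal direction
    and returns along the walls; the default sequence over-represents
    eastward crossings 3:1, producing strongly inhomogeneous directional
    sampling inside a central firing field while every direction still occurs
    there (the confound the pxd model is designed to remove).  Head direction
    is set to the running direction.
    """
    if config.arena_shape != "square":
        raise ValidationError("biased crossings are defined for square arenas")
    w = config.arena_width
    m, h = margin, w / 2.0
    A, B, C, D = (m, h), (w - m, h), (w - m, 2 * m), (m, 2 * m)
    T1, T2, TR = (h, m), (h, w - m), (w - m, w - m)
    loops = {
        "E": [C, D, A, B, C],
        "W": [C, B, A, D, C],
        "N": [C, T1, T2, TR, C],
        "S": [C, TR, T2, T1, C],
    }
    rate = config.position_rate
    dt = 1.0 / rate
    n = int(round(config.trial_duration * rate))
    xs: list = []
    ys: list = []
    x, y = C
    k = 0
    while len(xs) < n:
        loop = loops[sequence[k % len(sequence)]]
        k += 1
        for tgt in loop[1:]:
            while (x, y) != tgt and len(xs) < n:
                ddx, ddy = tgt[0] - x, tgt[1] - y
                d = math.hypot(ddx, ddy)
                step = min(speed * dt, d)
                x += step * ddx / d
                y += step * ddy / d
                xs.append(x)
                ys.append(y)
            if len(xs) >= n:
                break
    from .preprocess import derive_kinematics

    traj = derive_kinematics(
        Trajectory(t=np.arange(n) * dt, x=np.array(xs), y=np.array(ys), hd=np.zeros(n))
    )
    traj.hd = np.where(np.isfinite(traj.run_dir), traj.run_dir, 0.0)
    return traj


# ---------------------------------------------------------------------------
# firing-rate functions and spikes
# ---------------------------------------------------------------------------

def rate_on_trajectory(spec: CellSpec, traj: Trajectory, config: Optional[SessionConfig] = None) -> np.ndarray:
    """Generative firing rate (Hz) at every trajectory sample."""
    x, y, hd = traj.x, traj.y, traj.hd
    if spec.kind == "place":
        d2 = (x - spec.field_center[0]) ** 2 + (y - spec.field_center[1]) ** 2
        lam = spec.baseline_rate + spec.peak_rate * np.exp(-d2 / (2 * spec.field_sigma**2))
    elif spec.kind == "grid":
        lam = spec.baseline_rate + spec.peak_rate * grid_profile(
            x, y, spec.grid_spacing, spec.grid_orientation, spec.field_center
        )
    elif spec.kind == "hd":
        ang = np.deg2rad(hd - spec.hd_mu)
        lam = spec.baseline_rate + spec.peak_rate * np.exp(spec.hd_kappa * (np.cos(ang) - 1.0))
    elif spec.kind == "speed":
        v = traj.speed if traj.speed is not None else np.zeros_like(x)
        v = np.where(np.isfinite(v), v, 0.0)
        lam = np.clip(spec.baseline_rate + spec.speed_slope * v, 0.0, None)
    else:  # uniform
        lam = np.full_like(x, spec.peak_rate)
    if spec.kind in ("place", "grid") and spec.dir_mod_depth > 0:
        lam = lam * (1.0 + spec.dir_mod_depth * np.cos(np.deg2rad(hd - spec.hd_mu)))
    return np.clip(lam, 0.0, None)


def grid_profile(x, y, spacing, orientation_deg, anchor):
    """Three-cosine hexagonal lattice, rectified at 0 and normalised to [0, 1]."""
    k = 4.0 * math.pi / (math.sqrt(3.0) * spacing)
    out = np.zeros_like(np.asarray(x, dtype=float))
    dx = np.asarray(x) - anchor[0]
    dy = np.asarray(y) - anchor[1]
    for j in range(3):
        th = math.radians(orientation_deg + 60.0 * j)
        out = out + np.cos(k * (dx * math.cos(th) + dy * math.sin(th)))
    return np.clip(out, 0.0, None) / 3.0


def simulate_spikes(
    traj: Trajectory,
    spec: CellSpec,
    lfp: Optional[LFPSignal] = None,
    seed: int = 0,
    cell_id: str = "cell",
    config: Optional[SessionConfig] = None,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train by thinning at the trajectory rate.

    The intensity is piecewise constant over position samples; each sample
    contributes a Poisson count placed uniformly within its 20 ms interval.
    If ``spec.precession_range`` > 0 and an LFP is supplied, in-field spike
    times are nudged within their theta cycle so the spike phase regresses
    from late to early across the field traversal (wrapped-normal scatter
    around the target phase).
    """
    rng = np.random.default_rng(seed)
    dt = traj.dt
    lam = rate_on_trajectory(spec, traj, config)
    lam = np.where(traj.valid, lam, 0.0)
    counts = rng.poisson(lam * dt)
    total = int(counts.sum())
    idx = np.repeat(np.arange(traj.n), counts)
    times = traj.t[idx] + rng.uniform(0.0, dt, size=total)
    order = np.argsort(times, kind="stable")
    times = times[order]

    train = SpikeTrain(cell_id=cell_id, times=times).annotate(traj)
    if spec.precession_range > 0 and lfp is not None and total:
        train = _apply_precession(train, traj, spec, lfp, rng)
    return train


def _field_extent(spec: CellSpec) -> float:
    """Half-max field radius of the generative field (cm)."""
    if spec.kind == "place":
        return spec.field_sigma * math.sqrt(2.0 * math.log(2.0))
    # three-cosine bump: rate falls to half-peak at ≈ 0.195 × spacing
    return 0.195 * spec.grid_spacing


def _nearest_field_center(spec: CellSpec, x, y):
    if spec.kind == "place":
        cx = np.full_like(x, spec.field_center[0])
        cy = np.full_like(y, spec.field_center[1])
        return cx, cy
    # nearest node of the hexagonal lattice through the anchor
    th = math.radians(spec.grid_orientation)
    a1 = spec.grid_spacing * np.array([math.cos(th), math.sin(th)])
    a2 = spec.grid_spacing * np.array([math.cos(th + math.pi / 3), math.sin(th + math.pi / 3)])
    A = np.column_stack([a1, a2])
    Ainv = np.linalg.inv(A)
    rel = np.stack([np.asarray(x) - spec.field_center[0], np.asarray(y) - spec.field_center[1]])
    uv = Ainv @ rel
    best_d2 = np.full(rel.shape[1], np.inf)
    bx = np.empty(rel.shape[1])
    by = np.empty(rel.shape[1])
    u0 = np.floor(uv[0])
    v0 = np.floor(uv[1])
    for du in (0, 1):
        for dv in (0, 1):
            node = A @ np.stack([u0 + du, v0 + dv])
            d2 = (node[0] - rel[0]) ** 2 + (node[1] - rel[1]) ** 2
            better = d2 < best_d2
            best_d2[better] = d2[better]
            bx[better] = node[0][better]
            by[better] = node[1][better]
    return bx + spec.field_center[0], by + spec.field_center[1]


def _apply_precession(train, traj, spec, lfp, rng, phase_noise_sd=40.0, n_iter=3):
    from .theta import instantaneous_theta

    phase, freq = instantaneous_theta(lfp)
    ext = _field_extent(spec)
    noise = phase_noise_sd * rng.standard_normal(train.n_spikes)
    times = train.times.copy()
    t_max = traj.t[-1] + traj.dt - 1e-9

    def _pdcd(st):
        cx, cy = _nearest_field_center(spec, st.x, st.y)
        dx = st.x - cx
        dy = st.y - cy
        idx = st.sample_index
        run = traj.run_dir[idx] if traj.run_dir is not None else traj.hd[idx]
        run = np.where(np.isfinite(run), run, traj.hd[idx])
        ur = np.deg2rad(run)
        return np.hypot(dx, dy), np.clip((dx * np.cos(ur) + dy * np.sin(ur)) / ext, -1.0, 1.0)

    st = train
    order = np.arange(train.n_spikes)
    # iterate the time shift so the achieved phase matches the target at the
    # spike's final position (moving a spike changes its pdcd slightly)
    for _ in range(n_iter):
        r, pdcd = _pdcd(st)
        # the sweep covers the whole field bump and saturates at the half-max
        # edge (pdcd clipped to ±1), so spikes in the bump's outer tail carry
        # the sweep's end phase rather than an unrelated one
        in_field = r <= 1.5 * ext
        if not in_field.any():
            break
        target = 180.0 - 0.5 * spec.precession_range * pdcd + noise[order]
        li = np.clip(((times - lfp.t0) * lfp.rate).astype(int), 0, lfp.samples.size - 1)
        cur = phase[li]
        f = np.where(np.isfinite(freq[li]) & (freq[li] > 1.0), freq[li], DEFAULT_THETA_FREQ)
        shift = wrap_diff_deg(target - cur) / 360.0 / f
        times = np.where(in_field, np.clip(times + shift, 0.0, t_max), times)
        perm = np.argsort(times, kind="stable")
        times = times[perm]
        order = order[perm]
        st = SpikeTrain(cell_id=train.cell_id, times=times).annotate(traj)
    return st


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def simulate_lfp(
    traj: Trajectory,
    base_freq: float = DEFAULT_THETA_FREQ,
    speed_slope: float = DEFAULT_THETA_SLOPE,
    lfp_rate: float = 250.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> LFPSignal:
    """Phase-continuous theta oscillation with speed-coupled frequency."""
    if not 6.0 <= base_freq <= 10.0:
        raise ValidationError("base_freq must lie in the theta band (6-10 Hz)")
    v = traj.speed
    if v is None:
        v = np.zeros(traj.n)
    v = np.where(np.isfinite(v), v, 0.0)
    n_lfp = int(round(traj.duration * lfp_rate))
    t = np.arange(n_lfp) / lfp_rate
    v_lfp = np.interp(t, traj.t, v)
    freq = base_freq + speed_slope * v_lfp
    if lfp_rate < 4.0 * freq.max():
        raise ValidationError(
            f"lfp_rate {lfp_rate} Hz < 4× the maximum instantaneous frequency {freq.max():.2f} Hz"
        )
    phase = 2.0 * math.pi * np.cumsum(freq) / lfp_rate
    rng = np.random.default_rng(seed)
    samples = np.cos(phase) + noise_sd * rng.standard_normal(n_lfp)
    return LFPSignal(samples=samples, rate=lfp_rate)


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------

def make_session(
    config: SessionConfig,
    specs: Sequence[CellSpec],
    mean_speed: float = DEFAULT_MEAN_SPEED,
    wall_follow_bias: float = 0.0,
    base_freq: float = DEFAULT_THETA_FREQ,
    theta_speed_slope: float = DEFAULT_THETA_SLOPE,
    lfp_noise_sd: float = 0.2,
    seed: Optional[int] = None,
) -> Session:
    """Simulate a full session (trajectory, LFP, one spike train per spec)."""
    from .preprocess import derive_kinematics

    seed = config.rng_seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_traj, s_lfp, s_cells = ss.spawn(3)
    traj = simulate_trajectory(
        config,
        mean_speed=mean_speed,
        wall_follow_bias=wall_follow_bias,
        seed=s_traj,
    )
    traj = derive_kinematics(traj)
    lfp = simulate_lfp(
        traj,
        base_freq=base_freq,
        speed_slope=theta_speed_slope,
        lfp_rate=config.lfp_rate,
        noise_sd=lfp_noise_sd,
        seed=s_lfp,
    )
    cells = []
    for i, (spec, s) in enumerate(zip(specs, s_cells.spawn(len(specs)))):
        cells.append(
            simulate_spikes(traj, spec, lfp=lfp, seed=s, cell_id=f"cell{i:03d}", config=config)
        )
    gt = {
        "cells": [asdict(s) for s in specs],
        "mean_speed": mean_speed,
        "base_freq": base_freq,
        "theta_speed_slope": theta_speed_slope,
        "seed": int(seed) if isinstance(seed, (int, np.integer)) else None,
    }
    return Session(config=config, trajectory=traj, cells=cells, lfp=lfp, ground_truth=gt)


def apply_manipulation(spec: CellSpec, manip: VRManipulation, config: SessionConfig) -> CellSpec:
    """Transform one cell's generative parameters for the VR condition."""
    d = asdict(spec)
    if spec.kind == "place":
        d["field_sigma"] = spec.field_sigma * manip.scale_factor
        d["dir_mod_depth"] = min(1.0, spec.dir_mod_depth + manip.added_dir_mod)
    elif spec.kind == "grid":
        d["grid_spacing"] = spec.grid_spacing * manip.grid_scale_factor
    if manip.rotation == 180:
        cx = (config.arena_width / 2.0, config.arena_width / 2.0) if config.arena_shape == "square" else (0.0, 0.0)
        d["field_center"] = (2 * cx[0] - spec.field_center[0], 2 * cx[1] - spec.field_center[1])
        d["hd_mu"] = float(wrap_deg(spec.hd_mu + 180.0))
    return CellSpec(**d)


def make_vr_pair(
    base_specs: Sequence[CellSpec],
    manip: VRManipulation,
    config_r: SessionConfig,
    config_vr: SessionConfig,
    seed: int = 0,
    theta_speed_slope: float = DEFAULT_THETA_SLOPE,
    **kw,
) -> Tuple[Session, Session]:
    """Paired real/VR sessions sharing cell identities.

    The VR session applies the manipulation to every cell's generative
    parameters and to the LFP speed slope; trajectories are independent
    draws.
    """
    ss = np.random.SeedSequence(seed)
    s_r, s_vr = (int(s) % 2**31 for s in ss.generate_state(2))
    session_r = make_session(
        config_r, base_specs, theta_speed_slope=theta_speed_slope, seed=s_r, **kw
    )
    vr_specs = [apply_manipulation(s, manip, config_vr) for s in base_specs]
    session_vr = make_session(
        config_vr,
        vr_specs,
        theta_speed_slope=theta_speed_slope * manip.theta_slope_factor,
        seed=s_vr,
        **kw,
    )
    session_vr.ground_truth["manipulation"] = asdict(manip)
    return session_r, session_vr
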