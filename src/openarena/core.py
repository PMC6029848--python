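"""Core containers for open-arena spatial electrophysiology sessions.

Conventions used throughout the package:

* lengths in cm, times in seconds, angles in degrees.
* square arenas have their origin at a corner, so positions lie in
  ``[0, arena_width]``; cylindrical arenas have their origin at the arena
  centre, so positions lie inside the circle of radius ``arena_width / 2``.
* angles (head direction ``hd`` and running direction ``run_dir``) are
  counter-clockwise in ``[0, 360)`` with 0 pointing along +x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

ARENA_SHAPES = ("square", "cylinder")
CONDITIONS = ("VR", "R")


class ValidationError(ValueError):
    """A session component violates one of the container invariants."""


@dataclass
class SessionConfig:
    """Static description of one recording (or simulated) trial.

    Parameters
    ----------
    arena_shape:
        ``"square"`` or ``"cylinder"``.
    arena_width:
        Side length (square) or diameter (cylinder), cm.
    condition:
        ``"VR"`` (virtual reality) or ``"R"`` (real arena).
    trial_duration:
        Trial length in seconds.
    position_rate:
        Position sampling rate, Hz (overhead tracker / VR log, 50 Hz).
    lfp_rate:
        LFP sampling rate, Hz.
    bin_size:
        Side of the square spatial bins used for rate maps, cm.
    dir_bin:
        Width of directional bins, degrees.
    rng_seed:
        Seed used when this config drives the synthetic generator.
    """

    arena_shape: str = "square"
    arena_width: float = 60.0
    condition: str = "R"
    trial_duration: float = 2400.0
    position_rate: float = 50.0
    lfp_rate: float = 250.0
    bin_size: float = 1.5
    dir_bin: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.arena_shape not in ARENA_SHAPES:
            raise ValidationError(f"arena_shape must be one of {ARENA_SHAPES}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}")
        if self.arena_width <= 0:
            raise ValidationError("arena_width must be positive")
        if self.position_rate <= 0:
            raise ValidationError("position_rate must be positive")
        if self.trial_duration <= 0:
            raise ValidationError("trial_duration must be positive")
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        if not 0 < self.dir_bin <= 360:
            raise ValidationError("dir_bin must lie in (0, 360]")

    @property
    def n_bins(self) -> int:
        """Number of spatial bins per axis (``ceil(width / bin_size)``)."""
        return int(math.ceil(self.arena_width / self.bin_size - 1e-9))

    @property
    def n_dir_bins(self) -> int:
        return int(round(360.0 / self.dir_bin))

    def to_dict(self) -> dict:
        return {
            "arena_shape": self.arena_shape,
            "arena_width": float(self.arena_width),
            "condition": self.condition,
            "trial_duration": float(self.trial_duration),
            "position_rate": float(self.position_rate),
            "lfp_rate": float(self.lfp_rate),
            "bin_size": float(self.bin_size),
            "dir_bin": float(self.dir_bin),
            "rng_seed": int(self.rng_seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        return cls(**d)


def wrap_deg(a):
    """Wrap angles (deg) into [0, 360)."""
    return np.mod(a, 360.0)


def wrap_diff_deg(a):
    """Wrap angle differences (deg) into (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(a, dtype=float), 360.0)


@dataclass
class Trajectory:
    """Position samples on a regular grid with derived kinematics.

    ``speed`` and ``run_dir`` are filled by
    :func:`openarena.preprocess.derive_kinematics`; ``run_dir`` is NaN where
    undefined (stationary samples).  ``valid`` flags tracked samples; gaps
    left unfilled by interpolation stay invalid and are excluded downstream.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hd: np.ndarray
    speed: Optional[np.ndarray] = None
    run_dir: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.hd = np.asarray(self.hd, dtype=float)
        n = self.t.size
        for name in ("x", "y", "hd"):
            if getattr(self, name).size != n:
                raise ValidationError(f"trajectory field {name} has wrong length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("trajectory timestamps must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.speed is not None:
            self.speed = np.asarray(self.speed, dtype=float)
        if self.run_dir is not None:
            self.run_dir = np.asarray(self.run_dir, dtype=float)

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t))) if self.n > 1 else np.nan

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0] + self.dt) if self.n > 1 else 0.0

    def copy(self) -> "Trajectory":
        return Trajectory(
            t=self.t.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            hd=self.hd.copy(),
            speed=None if self.speed is None else self.speed.copy(),
            run_dir=None if self.run_dir is None else self.run_dir.copy(),
            valid=self.valid.copy(),
        )

    def nearest_sample(self, times) -> np.ndarray:
        """Index of the position sample nearest to each time."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.t, times)
        idx = np.clip(idx, 1, self.n - 1)
        left = times - self.t[idx - 1]
        right = self.t[idx] - times
        idx = idx - (left < right)
        return np.clip(idx, 0, self.n - 1)


@dataclass
class SpikeTrain:
    """Sorted spike times of one cell, with per-spike behavioural annotations.

    Annotations (position, head direction, speed, LFP theta phase, nearest
    position-sample index) are attached by :meth:`annotate`; the spatial
    analyses require them.
    """

    cell_id: str
    times: np.ndarray
    x: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    hd: Optional[np.ndarray] = None
    speed: Optional[np.ndarray] = None
    phase: Optional[np.ndarray] = None
    sample_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValidationError(f"cell {self.cell_id}: spike times must be sorted")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def annotate(self, traj: Trajectory) -> "SpikeTrain":
        """Attach per-spike behaviour by nearest position sample (in place)."""
        idx = traj.nearest_sample(self.times)
        self.sample_index = idx
        self.x = traj.x[idx]
        self.y = traj.y[idx]
        self.hd = traj.hd[idx]
        self.speed = None if traj.speed is None else traj.speed[idx]
        return self


@dataclass
class LFPSignal:
    """Single-channel local field potential trace (arbitrary units)."""

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValidationError("LFP rate must be positive")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class Session:
    """One trial: config, trajectory, spike trains and (optionally) LFP.

    ``ground_truth`` holds the generative parameters for synthetic sessions
    (used by recovery tests); it is ``None`` for recorded data.
    """

    config: SessionConfig
    trajectory: Trajectory
    cells: list = field(default_factory=list)
    lfp: Optional[LFPSignal] = None
    ground_truth: Optional[dict] = None

    def validate(self) -> "Session":
        T = self.config.trial_duration
        for cell in self.cells:
            if cell.n_spikes and (cell.times[0] < 0 or cell.times[-1] > T):
                raise ValidationError(
                    f"cell {cell.cell_id}: spike times outside [0, {T}]"
                )
        traj = self.trajectory
        if traj.n < 2:
            raise ValidationError("trajectory too short")
        expected = int(round(T * self.config.position_rate))
        if traj.n != expected:
            raise ValidationError(
                f"trajectory has {traj.n} samples, expected {expected} "
                f"({T} s at {self.config.position_rate} Hz)"
            )
        if not self._inside_arena(traj.x[traj.valid], traj.y[traj.valid]).all():
            raise ValidationError("trajectory leaves the arena")
        return self

    def _inside_arena(self, x, y, tol: float = 1e-6) -> np.ndarray:
        w = self.config.arena_width
        if self.config.arena_shape == "square":
            return (x >= -tol) & (x <= w + tol) & (y >= -tol) & (y <= w + tol)
        r = w / 2.0
        return x * x + y * y <= r * r + tol

    def cell(self, cell_id: str) -> SpikeTrain:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)
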