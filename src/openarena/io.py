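"""Session container I/O.

No public raw data accompany the recordings this package analyses, so the
on-disk format is a neutral directory of plain-text files:

``config.yaml``
    Session metadata (one key per :class:`~openarena.core.SessionConfig`
    field).
``positions.csv``
    Columns ``t,x,y,hd,valid`` at the configured position rate.
``spikes/<cell_id>.txt``
    One sorted spike time (s) per line, one file per cell.
``lfp.txt``
    One LFP sample per line (rate taken from the config).
``ground_truth.json``
    Optional generative parameters (synthetic sessions only).

Floats are written with 17 significant digits, so write → read round-trips
are bit exact.  Adapters for native acquisition formats (e.g. Axona) belong
outside this package; anything that can produce these text files can feed
the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import LFPSignal, Session, SessionConfig, SpikeTrain, Trajectory, ValidationError

_FLOAT_FMT = "%.17g"


def write_session(session: Session, path) -> None:
    """Write ``session`` as a directory container readable by :func:`read_session`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(session.config.to_dict(), fh, sort_keys=True)

    traj = session.trajectory
    df = pd.DataFrame(
        {
            "t": traj.t,
            "x": traj.x,
            "y": traj.y,
            "hd": traj.hd,
            "valid": traj.valid.astype(int),
        }
    )
    df.to_csv(path / "positions.csv", index=False, float_format=_FLOAT_FMT)

    spikes_dir = path / "spikes"
    spikes_dir.mkdir(exist_ok=True)
    for old in spikes_dir.glob("*.txt"):
        old.unlink()
    for cell in session.cells:
        np.savetxt(spikes_dir / f"{cell.cell_id}.txt", cell.times, fmt=_FLOAT_FMT)

    if session.lfp is not None:
        np.savetxt(path / "lfp.txt", session.lfp.samples, fmt=_FLOAT_FMT)

    if session.ground_truth is not None:
        with open(path / "ground_truth.json", "w") as fh:
            json.dump(session.ground_truth, fh, indent=1, sort_keys=True, default=_jsonify)


def read_session(path) -> Session:
    """Read a session container written by :func:`write_session`.

    All container invariants are checked on load; violations raise
    :class:`~openarena.core.ValidationError` naming the offending component.
    """
    path = Path(path)
    if not path.is_dir():
        raise ValidationError(f"session container {path} does not exist")
    cfg_path = path / "config.yaml"
    if not cfg_path.exists():
        raise ValidationError("missing session component: config.yaml")
    with open(cfg_path) as fh:
        config = SessionConfig.from_dict(yaml.safe_load(fh))

    pos_path = path / "positions.csv"
    if not pos_path.exists():
        raise ValidationError("missing session component: positions.csv")
    df = pd.read_csv(pos_path, float_precision="round_trip")
    for col in ("t", "x", "y", "hd"):
        if col not in df.columns:
            raise ValidationError(f"positions.csv missing column {col!r}")
    valid = (
        df["valid"].to_numpy().astype(bool)
        if "valid" in df.columns
        else np.ones(len(df), dtype=bool)
    )
    traj = Trajectory(
        t=df["t"].to_numpy(),
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        hd=df["hd"].to_numpy(),
        valid=valid,
    )

    cells = []
    spikes_dir = path / "spikes"
    if spikes_dir.is_dir():
        for f in sorted(spikes_dir.glob("*.txt")):
            times = np.loadtxt(f, ndmin=1) if f.stat().st_size else np.empty(0)
            cells.append(SpikeTrain(cell_id=f.stem, times=times))

    lfp = None
    lfp_path = path / "lfp.txt"
    if lfp_path.exists():
        samples = np.loadtxt(lfp_path, ndmin=1) if lfp_path.stat().st_size else np.empty(0)
        lfp = LFPSignal(samples=samples, rate=config.lfp_rate)

    ground_truth = None
    gt_path = path / "ground_truth.json"
    if gt_path.exists():
        with open(gt_path) as fh:
            ground_truth = json.load(fh)

    return Session(
        config=config, trajectory=traj, cells=cells, lfp=lfp, ground_truth=ground_truth
    ).validate()


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)!r}")
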