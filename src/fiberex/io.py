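"""Trajectory and report serialization: XYZ, GRO, CSV, JSON."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from fiberex.engine import CLASS_ORDER, System, Trajectory

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_gro",
    "write_json_report",
    "config_hash",
]

# element stand-ins for visualization tools (one per bead class)
_XYZ_NAMES = {"C1": "C", "C5": "S", "N0": "N", "CORE": "O", "CENTER": "P", "DIP": "H"}


def write_xyz(traj: Trajectory, path) -> None:
    """Multi-frame XYZ with the frame time in the comment line."""
    sys_ = traj.system
    names = [_XYZ_NAMES[CLASS_ORDER[c]] for c in sys_.class_idx]
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{sys_.n_beads}\n")
            fh.write(f"t= {traj.times[f]:.6f}\n")
            for name, (x, y, z) in zip(names, traj.frames[f]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a multi-frame XYZ written by :func:`write_xyz`.

    Returns (frames, times)."""
    frames, times = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        times.append(float(lines[i + 1].split()[-1]))
        rows = [
            [float(v) for v in lines[i + 2 + j].split()[1:4]] for j in range(n)
        ]
        frames.append(rows)
        i += 2 + n
    return np.array(frames), np.array(times)


def write_gro(sys_: System, path, positions: np.ndarray | None = None,
              box_nm_per_sigma: float = 0.47, title: str = "fiberex frame") -> None:
    """Single-frame GRO export (lengths converted with the nm mapping)."""
    pos = (positions if positions is not None else sys_.positions) * box_nm_per_sigma
    with open(path, "w") as fh:
        fh.write(f"{title}\n{sys_.n_beads}\n")
        for i in range(sys_.n_beads):
            resid = int(sys_.monomer_id[i]) + 1
            name = CLASS_ORDER[sys_.class_idx[i]][:5]
            fh.write(
                f"{resid:5d}{'MONO':<5s}{name:>5s}{i + 1:5d}"
                f"{pos[i, 0]:8.3f}{pos[i, 1]:8.3f}{pos[i, 2]:8.3f}\n"
            )
        ext = (pos.max(axis=0) - pos.min(axis=0)) + 2.0
        fh.write(f"{ext[0]:10.5f}{ext[1]:10.5f}{ext[2]:10.5f}\n")


def write_json_report(obj: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def config_hash(obj) -> str:
    """Stable short hash of a (nested, JSON-serializable) configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
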