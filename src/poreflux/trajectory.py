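"""Frame-indexed ion trajectories and their on-disk dialects.

An :class:`IonTrajectory` holds wrapped ion coordinates for every saved
frame together with the metadata the ionic-current estimator needs: the
per-ion charges, the saved-frame spacing (the dt entering the current
formula) and the periodic box lengths (whose z component is Lz).

Two plain-text dialects are supported:

* a multi-frame XYZ file (element column = species label, coordinates in
  nm) with a JSON metadata sidecar carrying charges, box and frame spacing;
* a single columnar CSV with columns
  ``frame, ion_id, species, charge, x, y, z`` (nm) plus the same sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IonTrajectory",
    "write_xyz",
    "read_xyz",
    "write_columnar",
    "read_columnar",
    "read_trajectory",
]

_SIDECAR_SUFFIX = ".meta.json"


@dataclass
class IonTrajectory:
    """Wrapped ion positions for T frames of n ions.

    Attributes
    ----------
    frames:
        Array of shape (T, n, 3), nm, wrapped into [0, box) per axis.
    charges:
        Per-ion charge in elementary charges (+1 / -1); must sum to zero.
    frame_spacing:
        Time between consecutive saved frames, ps.
    box_lengths:
        Periodic box (Lx, Ly, Lz), nm.
    species:
        Per-ion species labels (e.g. "K", "CL").
    """

    frames: np.ndarray
    charges: np.ndarray
    frame_spacing: float
    box_lengths: np.ndarray
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.box_lengths = np.asarray(self.box_lengths, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[-1] != 3:
            if self.frames.size == 0:
                self.frames = self.frames.reshape(0, len(self.charges), 3)
            else:
                raise ValueError(
                    f"frames must have shape (T, n, 3), got {self.frames.shape}"
                )
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive")
        if np.any(self.box_lengths <= 0):
            raise ValueError("box lengths must be positive")
        if self.n_frames and self.frames.shape[1] != self.charges.shape[0]:
            raise ValueError("charges length must match ion count")
        if abs(self.charges.sum()) > 1e-9:
            raise ValueError("ion charges must sum to zero (electroneutrality)")
        if not self.species:
            self.species = ["X"] * self.charges.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_ions(self) -> int:
        return self.charges.shape[0]

    @property
    def lz(self) -> float:
        return float(self.box_lengths[2])


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + _SIDECAR_SUFFIX)


def _write_sidecar(path: Path, traj: IonTrajectory) -> None:
    meta = {
        "frame_spacing_ps": traj.frame_spacing,
        "box_lengths_nm": traj.box_lengths.tolist(),
        "charges_e": traj.charges.tolist(),
        "species": list(traj.species),
        "n_frames": traj.n_frames,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"metadata sidecar {sidecar} not found next to {path}"
        )
    return json.loads(sidecar.read_text())


def write_xyz(traj: IonTrajectory, path: str | Path) -> Path:
    """Write a multi-frame XYZ file (nm) plus a JSON metadata sidecar."""
    path = Path(path)
    n = traj.n_ions
    with path.open("w") as fh:
        for t in range(traj.n_frames):
            fh.write(f"{n}\n")
            fh.write(f"frame={t} units=nm dt_ps={traj.frame_spacing!r}\n")
            for i in range(n):
                x, y, z = (float(v) for v in traj.frames[t, i])
                fh.write(f"{traj.species[i]} {x!r} {y!r} {z!r}\n")
    _write_sidecar(path, traj)
    return path


def read_xyz(path: str | Path) -> IonTrajectory:
    """Read a multi-frame XYZ trajectory written by :func:`write_xyz`.

    Any multi-frame XYZ with constant atom count is accepted as long as a
    metadata sidecar provides charges, box lengths and frame spacing.
    """
    path = Path(path)
    meta = _read_sidecar(path)
    frames: list[np.ndarray] = []
    species: list[str] = []
    with path.open() as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()  # comment line
            coords = np.empty((n, 3))
            labels = []
            for i in range(n):
                parts = fh.readline().split()
                labels.append(parts[0])
                coords[i] = [float(v) for v in parts[1:4]]
            frames.append(coords)
            species = labels
    if not species:
        species = list(meta.get("species", []))
    arr = (
        np.stack(frames)
        if frames
        else np.empty((0, len(meta["charges_e"]), 3))
    )
    return IonTrajectory(
        frames=arr,
        charges=np.asarray(meta["charges_e"]),
        frame_spacing=float(meta["frame_spacing_ps"]),
        box_lengths=np.asarray(meta["box_lengths_nm"]),
        species=species,
    )


def write_columnar(traj: IonTrajectory, path: str | Path) -> Path:
    """Write the columnar CSV dialect plus the JSON metadata sidecar."""
    path = Path(path)
    t_idx = np.repeat(np.arange(traj.n_frames), traj.n_ions)
    i_idx = np.tile(np.arange(traj.n_ions), traj.n_frames)
    flat = traj.frames.reshape(-1, 3) if traj.n_frames else np.empty((0, 3))
    df = pd.DataFrame(
        {
            "frame": t_idx,
            "ion_id": i_idx,
            "species": [traj.species[i] for i in i_idx],
            "charge": traj.charges[i_idx] if len(i_idx) else [],
            "x": flat[:, 0],
            "y": flat[:, 1],
            "z": flat[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    _write_sidecar(path, traj)
    return path


def read_columnar(path: str | Path) -> IonTrajectory:
    """Read the columnar CSV dialect written by :func:`write_columnar`."""
    path = Path(path)
    meta = _read_sidecar(path)
    df = pd.read_csv(path)
    n_ions = len(meta["charges_e"])
    if len(df):
        n_frames = int(df["frame"].max()) + 1
        df = df.sort_values(["frame", "ion_id"])
        arr = df[["x", "y", "z"]].to_numpy().reshape(n_frames, n_ions, 3)
        species = list(df["species"].iloc[:n_ions])
    else:
        arr = np.empty((0, n_ions, 3))
        species = list(meta.get("species", []))
    return IonTrajectory(
        frames=arr,
        charges=np.asarray(meta["charges_e"]),
        frame_spacing=float(meta["frame_spacing_ps"]),
        box_lengths=np.asarray(meta["box_lengths_nm"]),
        species=species,
    )


def read_trajectory(path: str | Path) -> IonTrajectory:
    """Dispatch on file extension: .xyz -> XYZ dialect, else columnar CSV."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        return read_xyz(path)
    return read_columnar(path)
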