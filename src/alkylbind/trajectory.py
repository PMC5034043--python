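"""Trajectory container and XYZ-with-sidecar I/O.

A trajectory is an ordered stack of frames over a fixed atom roster. Atom
roles (donor / hydrogen / acceptor / other) and group membership live in a
sidecar JSON file because plain XYZ has nowhere to put them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

ROLES = ("donor", "hydrogen", "acceptor", "other")


@dataclass(frozen=True)
class Atom:
    """One atom of the fixed roster.

    ``parent`` is the id of the covalently attached donor for atoms with
    role ``hydrogen`` and ``None`` otherwise.
    """

    id: str
    element: str
    role: str
    group: str
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.role == "hydrogen" and self.parent is None:
            raise ValueError(f"hydrogen atom {self.id!r} needs a parent donor id")


@dataclass
class Trajectory:
    """Coordinate frames (n_frames, n_atoms, 3) in angstroms plus metadata."""

    atoms: list[Atom]
    coords: np.ndarray
    frame_interval: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"{len(self.atoms)} atoms but coords have {self.coords.shape[1]} columns"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates in trajectory")
        ids = [a.id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate atom ids")
        by_id = {a.id: a for a in self.atoms}
        for a in self.atoms:
            if a.role == "hydrogen" and by_id.get(a.parent) is None:
                raise ValueError(f"hydrogen {a.id!r} references missing parent {a.parent!r}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index_of(self, atom_id: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.id == atom_id:
                return i
        raise KeyError(atom_id)

    def atoms_in_group(self, group: str) -> list[Atom]:
        return [a for a in self.atoms if a.group == group]


def write_xyz(traj: Trajectory, xyz_path: str | Path, roles_path: str | Path | None = None) -> None:
    """Write frames as multi-frame XYZ; roles/groups/metadata to a JSON sidecar.

    The per-frame comment line carries the coupling parameter (if present in
    metadata) and the frame index, e.g. ``lambda=1.0 frame=12``.
    """
    xyz_path = Path(xyz_path)
    lam = traj.metadata.get("lambda")
    lam_txt = "" if lam is None else f"lambda={lam} "
    with open(xyz_path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n{lam_txt}frame={f}\n")
            for a, (x, y, z) in zip(traj.atoms, traj.coords[f]):
                fh.write(f"{a.element} {x:.6f} {y:.6f} {z:.6f}\n")
    if roles_path is None:
        roles_path = xyz_path.with_suffix(".roles.json")
    sidecar = {
        "atoms": [
            {"id": a.id, "element": a.element, "role": a.role, "group": a.group, "parent": a.parent}
            for a in traj.atoms
        ],
        "frame_interval": traj.frame_interval,
        "metadata": traj.metadata,
    }
    Path(roles_path).write_text(json.dumps(sidecar, indent=1))


def read_xyz(xyz_path: str | Path, roles_path: str | Path | None = None) -> Trajectory:
    """Read a trajectory written by :func:`write_xyz`."""
    xyz_path = Path(xyz_path)
    if roles_path is None:
        roles_path = xyz_path.with_suffix(".roles.json")
    sidecar = json.loads(Path(roles_path).read_text())
    atoms = [Atom(**rec) for rec in sidecar["atoms"]]

    frames: list[list[list[float]]] = []
    lines = xyz_path.read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        if len(block) != n:
            raise ValueError(f"truncated XYZ frame at line {i}")
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + n
    return Trajectory(
        atoms=atoms,
        coords=np.asarray(frames, dtype=float),
        frame_interval=float(sidecar.get("frame_interval", 1.0)),
        metadata=sidecar.get("metadata", {}),
    )


def energies_to_csv(energies: Sequence[float], path: str | Path) -> None:
    """Export per-frame site energies (kcal/mol) as a two-column CSV."""
    with open(path, "w") as fh:
        fh.write("frame,u_site_kcal_mol\n")
        for i, u in enumerate(energies):
            fh.write(f"{i},{u:.10g}\n")
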