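"""Periodic-box multi-frame coordinate model with explicit molecule grouping.

Formats supported are the plain-text ones used around Gromacs-style
workflows: multi-frame GRO (fixed-column, nm), multi-frame XYZ whose comment
line carries ``time=<ps> box=<Lx>,<Ly>,<Lz>`` metadata (Å), and PDB with
CRYST1/MODEL records.  Boxes are orthorhombic; lengths are stored in Å
internally (GRO's nm converted at the boundary).

Molecule grouping is supplied explicitly rather than perceived from
chemistry: residue-based for GRO/PDB, fixed-size blocks for XYZ, or a fully
explicit atom-index map.  The grouping also names each molecule's aromatic
ring atoms, which downstream stacking classification needs.  Atoms not
covered by the grouping (typically the octanol solvent) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping, Sequence

import numpy as np

from ._util import min_image_distance, min_image_vector  # re-exported

__all__ = [
    "MoleculeTopology", "Frame", "Trajectory",
    "read_trajectory", "write_trajectory",
    "min_image_distance", "min_image_vector",
    "TrajectoryError", "ParseError",
]


class TrajectoryError(ValueError):
    """Trajectory-level validation failure."""


class ParseError(TrajectoryError):
    """Malformed record in a coordinate file."""

    def __init__(self, path: Any, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class MoleculeTopology:
    """One molecule: its global atom indices, elements and ring definitions."""

    molecule_id: str
    atom_indices: tuple[int, ...]
    elements: tuple[str, ...]
    rings: tuple[tuple[int, ...], ...] = ()  # global atom indices, one tuple per ring

    def __post_init__(self) -> None:
        if not self.atom_indices:
            raise TrajectoryError(f"{self.molecule_id}: empty atom list")
        if len(self.elements) != len(self.atom_indices):
            raise TrajectoryError(f"{self.molecule_id}: element/atom count mismatch")
        atoms = set(self.atom_indices)
        for ring in self.rings:
            if len(ring) < 5:
                raise TrajectoryError(f"{self.molecule_id}: ring with < 5 atoms")
            if not set(ring) <= atoms:
                raise TrajectoryError(f"{self.molecule_id}: ring references atoms outside molecule")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)


@dataclass
class Frame:
    """A snapshot: time (ps), orthorhombic box edges (Å), atom coordinates (Å)."""

    time: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if np.any(self.box <= 0):
            raise TrajectoryError(f"frame t={self.time}: box edges must be positive")


@dataclass
class Trajectory:
    """An ordered frame sequence over a fixed molecule topology."""

    topology: list[MoleculeTopology]
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for mol in self.topology:
            overlap = seen & set(mol.atom_indices)
            if overlap:
                raise TrajectoryError(
                    f"molecule {mol.molecule_id}: atom indices {sorted(overlap)} already assigned")
            seen |= set(mol.atom_indices)
        n_atoms = self.n_atoms
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise TrajectoryError("frame times must be strictly increasing")
        for f in self.frames:
            if f.coords.shape[0] != n_atoms:
                raise TrajectoryError(
                    f"frame t={f.time}: {f.coords.shape[0]} coordinates for {n_atoms} topology atoms")

    @property
    def n_atoms(self) -> int:
        return sum(m.n_atoms for m in self.topology)

    @property
    def n_molecules(self) -> int:
        return len(self.topology)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([f.time for f in self.frames])

    def molecule(self, molecule_id: str) -> MoleculeTopology:
        for mol in self.topology:
            if mol.molecule_id == molecule_id:
                return mol
        raise KeyError(f"unknown molecule id {molecule_id!r}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)


# ---------------------------------------------------------------------------
# grouping

def _apply_grouping(grouping: Mapping[str, Any],
                    elements: Sequence[str],
                    per_atom_resid: Sequence[int] | None,
                    per_atom_resname: Sequence[str] | None,
                    raw_frames: list[Frame]) -> Trajectory:
    """Select and group atoms, compact coordinates, and build the Trajectory."""
    mode = grouping.get("mode", "uniform")
    molecules_raw: list[tuple[str, list[int], list[list[int]]]] = []  # id, global atoms, local rings

    if mode == "uniform":
        n_mol = int(grouping["n_molecules"])
        per = int(grouping["atoms_per_molecule"])
        if n_mol * per > len(elements):
            raise TrajectoryError(
                f"grouping references absent atoms: {n_mol}x{per} > {len(elements)} atoms in file")
        rings = [list(map(int, r)) for r in grouping.get("rings", [])]
        prefix = grouping.get("id_prefix", "mol")
        for i in range(n_mol):
            start = i * per
            molecules_raw.append((f"{prefix}-{i}", list(range(start, start + per)), rings))
    elif mode == "residue":
        if per_atom_resid is None:
            raise TrajectoryError("residue grouping requires a format with residue records (GRO/PDB)")
        keep = grouping.get("resnames")
        rings = [list(map(int, r)) for r in grouping.get("rings", [])]
        runs: list[tuple[int, str, list[int]]] = []
        for idx, (rid, rname) in enumerate(zip(per_atom_resid, per_atom_resname)):
            if runs and runs[-1][0] == rid and runs[-1][1] == rname:
                runs[-1][2].append(idx)
            else:
                runs.append((rid, rname, [idx]))
        for rid, rname, atoms in runs:
            if keep is not None and rname not in keep:
                continue
            molecules_raw.append((f"{rname}-{rid}", atoms, rings))
        if not molecules_raw:
            raise TrajectoryError(f"grouping selected no molecules (resnames={keep})")
    elif mode == "explicit":
        for spec in grouping["molecules"]:
            atoms = [int(a) for a in spec["atoms"]]
            if any(a >= len(elements) or a < 0 for a in atoms):
                raise TrajectoryError(
                    f"molecule {spec.get('id')}: grouping references absent atoms")
            rings = [list(map(int, r)) for r in spec.get("rings", [])]
            molecules_raw.append((str(spec["id"]), atoms, rings))
    else:
        raise TrajectoryError(f"unknown grouping mode {mode!r}")

    # compact to the selected atoms, reindexing from zero
    order: list[int] = []
    topo: list[MoleculeTopology] = []
    for mol_id, atoms, local_rings in molecules_raw:
        base = len(order)
        order.extend(atoms)
        for ring in local_rings:
            if any(r < 0 or r >= len(atoms) for r in ring):
                raise TrajectoryError(f"molecule {mol_id}: ring index outside molecule")
        topo.append(MoleculeTopology(
            molecule_id=mol_id,
            atom_indices=tuple(range(base, base + len(atoms))),
            elements=tuple(elements[a] for a in atoms),
            rings=tuple(tuple(base + r for r in ring) for ring in local_rings),
        ))
    sel = np.asarray(order, dtype=int)
    frames = [Frame(f.time, f.box, f.coords[sel]) for f in raw_frames]
    return Trajectory(topology=topo, frames=frames)


# ---------------------------------------------------------------------------
# readers

def _read_xyz(path: Path) -> tuple[list[str], None, None, list[Frame]]:
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    elements: list[str] = []
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].split()[0])
        except ValueError:
            raise ParseError(path, i + 1, f"expected atom count, got {lines[i]!r}")
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0 and i + 1 + natoms > len(lines):
            raise ParseError(path, i + 1, "truncated frame")
        comment = lines[i + 1]
        time, box = _parse_xyz_comment(comment, frame_idx)
        coords = np.empty((natoms, 3))
        frame_elements: list[str] = []
        for j in range(natoms):
            ln = i + 2 + j
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(path, ln + 1, f"malformed atom record {lines[ln]!r}")
            frame_elements.append(parts[0])
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise ParseError(path, ln + 1, f"non-numeric coordinate in {lines[ln]!r}")
        if not elements:
            elements = frame_elements
        if box is None:
            raise ParseError(path, i + 2, "XYZ comment line must carry box=Lx,Ly,Lz")
        frames.append(Frame(time=time, box=box, coords=coords))
        i += 2 + natoms
        frame_idx += 1
    return elements, None, None, frames


def _parse_xyz_comment(comment: str, frame_idx: int) -> tuple[float, np.ndarray | None]:
    time = float(frame_idx)
    box = None
    for token in comment.split():
        if token.startswith("time="):
            time = float(token[5:])
        elif token.startswith("box="):
            vals = [float(v) for v in token[4:].split(",")]
            if len(vals) == 1:
                vals = vals * 3
            box = np.asarray(vals[:3])
    return time, box


def _read_gro(path: Path) -> tuple[list[str], list[int], list[str], list[Frame]]:
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    elements: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        time = float(frame_idx)
        if " t=" in title:
            try:
                time = float(title.split(" t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        try:
            natoms = int(lines[i + 1].split()[0])
        except (ValueError, IndexError):
            raise ParseError(path, i + 2, "expected atom count")
        coords = np.empty((natoms, 3))
        frame_elements, frame_resids, frame_resnames = [], [], []
        for j in range(natoms):
            ln = i + 2 + j
            line = lines[ln]
            try:
                frame_resids.append(int(line[0:5]))
                frame_resnames.append(line[5:10].strip())
                atom_name = line[10:15].strip()
                # nm -> Angstrom; velocity columns (if present) are discarded
                coords[j] = [float(line[20:28]) * 10.0,
                             float(line[28:36]) * 10.0,
                             float(line[36:44]) * 10.0]
            except (ValueError, IndexError):
                raise ParseError(path, ln + 1, f"malformed GRO atom record {line!r}")
            frame_elements.append(_element_from_name(atom_name))
        box_ln = i + 2 + natoms
        box_vals = [float(v) for v in lines[box_ln].split()]
        if len(box_vals) > 3 and any(abs(v) > 1e-12 for v in box_vals[3:]):
            raise TrajectoryError(
                f"{path}:{box_ln + 1}: triclinic box not supported (orthorhombic only)")
        box = np.asarray(box_vals[:3]) * 10.0
        if not elements:
            elements, resids, resnames = frame_elements, frame_resids, frame_resnames
        frames.append(Frame(time=time, box=box, coords=coords))
        i = box_ln + 1
        frame_idx += 1
    return elements, resids, resnames, frames


def _read_pdb(path: Path) -> tuple[list[str], list[int], list[str], list[Frame]]:
    box: np.ndarray | None = None
    frames: list[Frame] = []
    elements: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    cur: list[list[float]] = []
    cur_time: float | None = None
    frame_idx = 0
    first_model = True

    def flush() -> None:
        nonlocal cur, frame_idx, cur_time, first_model
        if not cur:
            return
        if box is None:
            raise TrajectoryError(f"{path}: missing CRYST1 record")
        t = cur_time if cur_time is not None else float(frame_idx)
        frames.append(Frame(time=t, box=box, coords=np.asarray(cur)))
        cur = []
        cur_time = None
        frame_idx += 1
        first_model = False

    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
            angles = [float(line[33:40]), float(line[40:47]), float(line[47:54])]
            if any(abs(x - 90.0) > 1e-3 for x in angles):
                raise TrajectoryError(f"{path}:{lineno}: non-orthorhombic cell not supported")
            box = np.asarray([a, b, c])
        elif rec == "MODEL":
            cur = []
        elif rec in ("ATOM", "HETATM"):
            try:
                if first_model:
                    resnames.append(line[17:20].strip())
                    resids.append(int(line[22:26]))
                    el = line[76:78].strip() or _element_from_name(line[12:16].strip())
                    elements.append(el)
                cur.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            except (ValueError, IndexError):
                raise ParseError(path, lineno, f"malformed PDB atom record {line!r}")
        elif rec == "ENDMDL":
            flush()
        elif rec == "REMARK" and "time=" in line:
            cur_time = float(line.split("time=")[1].split()[0])
    flush()
    return elements, resids, resnames, frames


def _element_from_name(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Br"):
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "X"


def read_trajectory(path: str | Path, format: str,
                    grouping: Mapping[str, Any]) -> Trajectory:
    """Read a trajectory file and apply the molecule grouping spec.

    ``format`` is one of ``gro``, ``xyz``, ``pdb``.  The grouping spec (a
    mapping, typically loaded from YAML) selects solute atoms, partitions
    them into molecules and names each molecule's ring atoms; see the module
    docstring for the three modes.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "xyz":
        elements, resids, resnames, frames = _read_xyz(path)
    elif fmt == "gro":
        elements, resids, resnames, frames = _read_gro(path)
    elif fmt == "pdb":
        elements, resids, resnames, frames = _read_pdb(path)
    else:
        raise TrajectoryError(f"unknown format {format!r} (expected gro, xyz or pdb)")
    if not frames:
        raise TrajectoryError(f"{path}: no frames found")
    return _apply_grouping(grouping, elements, resids, resnames, frames)


# ---------------------------------------------------------------------------
# writers

def write_trajectory(traj: Trajectory, path: str | Path, format: str) -> None:
    """Write a trajectory in GRO, XYZ or PDB form (solute atoms only)."""
    if not traj.frames:
        raise TrajectoryError("cannot write a trajectory with no frames")
    path = Path(path)
    fmt = format.lower()
    if fmt == "xyz":
        _write_xyz(traj, path)
    elif fmt == "gro":
        _write_gro(traj, path)
    elif fmt == "pdb":
        _write_pdb(traj, path)
    else:
        raise TrajectoryError(f"unknown format {format!r} (expected gro, xyz or pdb)")


def _iter_atoms(traj: Trajectory):
    for mol_i, mol in enumerate(traj.topology):
        for local, (gidx, el) in enumerate(zip(mol.atom_indices, mol.elements)):
            yield mol_i, mol, local, gidx, el


def _write_xyz(traj: Trajectory, path: Path) -> None:
    atoms = list(_iter_atoms(traj))
    with open(path, "w") as fh:
        for frame in traj.frames:
            bx = ",".join(f"{v:.6f}" for v in frame.box)
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"time={frame.time:.6f} box={bx}\n")
            for _, _, _, gidx, el in atoms:
                x, y, z = frame.coords[gidx]
                fh.write(f"{el:<3s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def _write_gro(traj: Trajectory, path: Path) -> None:
    atoms = list(_iter_atoms(traj))
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"octagg frame t= {frame.time:.4f}\n")
            fh.write(f"{traj.n_atoms:5d}\n")
            serial = 0
            for mol_i, _mol, local, gidx, el in atoms:
                serial += 1
                x, y, z = frame.coords[gidx] / 10.0  # Angstrom -> nm
                name = f"{el}{local + 1}"
                fh.write(f"{(mol_i + 1) % 100000:5d}{'MOL':<5s}{name:>5s}{serial % 100000:5d}"
                         f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
            bx = frame.box / 10.0
            fh.write(f"{bx[0]:10.5f}{bx[1]:10.5f}{bx[2]:10.5f}\n")


def _write_pdb(traj: Trajectory, path: Path) -> None:
    atoms = list(_iter_atoms(traj))
    with open(path, "w") as fh:
        box = traj.frames[0].box
        fh.write(f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                 f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        for model, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {model:4d}\n")
            fh.write(f"REMARK time={frame.time:.6f}\n")
            serial = 0
            for mol_i, _mol, local, gidx, el in atoms:
                serial += 1
                x, y, z = frame.coords[gidx]
                name = f"{el}{local + 1}"[:4]
                fh.write(f"ATOM  {serial % 100000:5d} {name:<4s} MOL A{(mol_i + 1) % 10000:4d}    "
                         f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {el:>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")
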