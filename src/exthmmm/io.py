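"""Readers and writers for PDB structures and DCD/XTC trajectories.

Thin adapters between the toolkit's :class:`MolecularSystem` /
:class:`TrajectoryEnsemble` containers and MDAnalysis, which handles the
actual file formats.  Trajectory writing adds a small JSON sidecar with
per-frame times in ns (binary trajectory formats do not reliably
round-trip absolute times).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterator

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .core import Frame, MolecularSystem, TrajectoryEnsemble

__all__ = [
    "read_structure",
    "write_pdb",
    "write_trajectory",
    "read_trajectory",
    "iter_trajectory",
]


def _guess_element(name: str) -> str:
    name = name.strip()
    if name[:2].upper() in ("CL", "NA", "MG", "BR"):
        return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def to_universe(system: MolecularSystem,
                tempfactors: np.ndarray | None = None) -> mda.Universe:
    """Build an in-memory MDAnalysis Universe mirroring the system."""
    n = system.n_atoms
    resnum = system.residue_number
    # compress consecutive-residue records into MDAnalysis residue indices
    boundaries = np.flatnonzero(np.diff(resnum) != 0)
    starts = np.concatenate([[0], boundaries + 1])
    resindex = np.zeros(n, dtype=np.int64)
    for ri, s in enumerate(starts):
        e = starts[ri + 1] if ri + 1 < len(starts) else n
        resindex[s:e] = ri
    res_segids = system.segment_id.astype(str)[starts]
    seg_labels = list(dict.fromkeys(res_segids))
    seg_index = {s: i for i, s in enumerate(seg_labels)}
    u = mda.Universe.empty(
        n_atoms=n, n_residues=len(starts), n_segments=len(seg_labels),
        atom_resindex=resindex,
        residue_segindex=np.array([seg_index[s] for s in res_segids]),
        trajectory=True,
    )
    u.add_TopologyAttr("names", system.atom_name.astype(str))
    u.add_TopologyAttr("elements", system.element.astype(str))
    u.add_TopologyAttr("resids", resnum[starts])
    u.add_TopologyAttr("resnames", system.residue_name.astype(str)[starts])
    u.add_TopologyAttr("segids", seg_labels)
    u.add_TopologyAttr("tempfactors",
                       np.zeros(n) if tempfactors is None else tempfactors)
    u.add_TopologyAttr("occupancies", np.ones(n))
    u.atoms.positions = system.coordinates.astype(np.float32)
    if system.box is not None:
        u.dimensions = [*system.box, 90.0, 90.0, 90.0]
    return u


def write_pdb(system: MolecularSystem, path: str | Path,
              tempfactors: np.ndarray | None = None) -> None:
    """Write a PDB file (CRYST1 record included when a box is set)."""
    u = to_universe(system, tempfactors=tempfactors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_structure(path: str | Path) -> MolecularSystem:
    """Read a PDB file into a MolecularSystem (atoms in file order)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = u.atoms
    try:
        elements = atoms.elements.astype(object)
        if any(str(e).strip() == "" for e in elements):
            raise AttributeError
    except Exception:
        elements = np.array([_guess_element(n) for n in atoms.names],
                            dtype=object)
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = np.asarray(u.dimensions[:3], dtype=np.float64)
    return MolecularSystem(
        atom_name=atoms.names.astype(object),
        residue_number=atoms.resids.astype(np.int64),
        residue_name=atoms.resnames.astype(object),
        segment_id=atoms.segids.astype(object),
        element=elements,
        coordinates=atoms.positions.astype(np.float64),
        box=box,
    )


def _times_sidecar(traj_path: str | Path) -> Path:
    return Path(str(traj_path) + ".times.json")


def write_trajectory(traj: TrajectoryEnsemble, topology_path: str | Path,
                     trajectory_path: str | Path) -> None:
    """Write topology PDB + binary trajectory (format from the file
    extension: .dcd or .xtc) + times sidecar."""
    write_pdb(traj.topology, topology_path)
    u = to_universe(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(trajectory_path),
                        n_atoms=traj.topology.n_atoms) as w:
            for i, frame in enumerate(traj):
                u.atoms.positions = frame.coordinates.astype(np.float32)
                if frame.box is not None:
                    u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
                u.trajectory.ts.time = frame.time * 1000.0  # ps
                u.trajectory.ts.frame = i
                w.write(u.atoms)
    _times_sidecar(trajectory_path).write_text(
        json.dumps({"time_ns": [float(t) for t in traj.time]})
    )


def iter_trajectory(topology_path: str | Path,
                    trajectory_path: str | Path) -> Iterator[Frame]:
    """Stream frames from disk without materializing the trajectory."""
    top = read_structure(topology_path)
    times = None
    sidecar = _times_sidecar(trajectory_path)
    if sidecar.exists():
        times = json.loads(sidecar.read_text())["time_ns"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path), str(trajectory_path))
    if u.atoms.n_atoms != top.n_atoms:
        raise ValueError(
            f"atom-count mismatch: topology has {top.n_atoms}, "
            f"trajectory has {u.atoms.n_atoms}"
        )
    for i, ts in enumerate(u.trajectory):
        box = None
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box = np.asarray(ts.dimensions[:3], dtype=np.float64)
        t = times[i] if times is not None else float(ts.time) / 1000.0
        yield Frame(ts.positions.astype(np.float64), box, float(t))


def read_trajectory(topology_path: str | Path,
                    trajectory_path: str | Path) -> TrajectoryEnsemble:
    """Load a trajectory into memory as a TrajectoryEnsemble."""
    top = read_structure(topology_path)
    coords, boxes, times = [], [], []
    for frame in iter_trajectory(topology_path, trajectory_path):
        coords.append(frame.coordinates)
        boxes.append(frame.box)
        times.append(frame.time)
    if not coords:
        raise ValueError(f"empty trajectory: {trajectory_path}")
    box = None
    if all(b is not None for b in boxes):
        box = np.stack(boxes)
    return TrajectoryEnsemble(top, np.stack(coords), np.asarray(times), box)
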