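"""Structural data model, named selections, and geometry primitives.

Everything downstream (patch building, binding metrics, contact and
insertion analysis, RMSD) operates on :class:`MolecularSystem` /
:class:`TrajectoryEnsemble` and resolves atoms through
:class:`SelectionSpec`.  Coordinates are in Angstrom throughout; the
flat-bottom restraint module converts to nm at its own boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "MolecularSystem",
    "Frame",
    "TrajectoryEnsemble",
    "SelectionSpec",
    "DomainDefinitions",
    "resolve_selection",
    "centroid",
    "angle_deg",
    "dihedral_deg",
]

# Approximate atomic masses for the optional mass-weighted centroid.
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "CL": 35.45, "NA": 22.990, "K": 39.098, "CA": 40.078,
}


@dataclass
class MolecularSystem:
    """A set of atoms with coordinates — the single structural currency.

    Parallel arrays indexed by atom; ``atom_index`` is 0-based, unique and
    contiguous.  ``box`` is the optional (Lx, Ly, Lz) orthorhombic cell in
    Angstrom.
    """

    atom_name: np.ndarray
    residue_number: np.ndarray
    residue_name: np.ndarray
    segment_id: np.ndarray
    element: np.ndarray
    coordinates: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.residue_number = np.asarray(self.residue_number, dtype=np.int64)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.segment_id = np.asarray(self.segment_id, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        n = len(self.atom_name)
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{n} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64).reshape(3)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def atom_index(self) -> np.ndarray:
        return np.arange(self.n_atoms, dtype=np.int64)

    def masses(self) -> np.ndarray:
        return np.array(
            [_ELEMENT_MASSES.get(str(e).upper(), 12.011) for e in self.element]
        )

    def subset(self, indices: Sequence[int]) -> "MolecularSystem":
        idx = np.asarray(indices, dtype=np.int64)
        return MolecularSystem(
            atom_name=self.atom_name[idx],
            residue_number=self.residue_number[idx],
            residue_name=self.residue_name[idx],
            segment_id=self.segment_id[idx],
            element=self.element[idx],
            coordinates=self.coordinates[idx],
            box=None if self.box is None else self.box.copy(),
        )

    def with_coordinates(self, coords: np.ndarray) -> "MolecularSystem":
        out = MolecularSystem(
            atom_name=self.atom_name,
            residue_number=self.residue_number,
            residue_name=self.residue_name,
            segment_id=self.segment_id,
            element=self.element,
            coordinates=np.asarray(coords, dtype=np.float64),
            box=None if self.box is None else self.box.copy(),
        )
        return out

    @staticmethod
    def concatenate(systems: Sequence["MolecularSystem"],
                    box: np.ndarray | None = None) -> "MolecularSystem":
        return MolecularSystem(
            atom_name=np.concatenate([s.atom_name for s in systems]),
            residue_number=np.concatenate([s.residue_number for s in systems]),
            residue_name=np.concatenate([s.residue_name for s in systems]),
            segment_id=np.concatenate([s.segment_id for s in systems]),
            element=np.concatenate([s.element for s in systems]),
            coordinates=np.vstack([s.coordinates for s in systems]),
            box=box,
        )


@dataclass
class Frame:
    """One trajectory frame: coordinates (Angstrom), box, time (ns)."""

    coordinates: np.ndarray
    box: np.ndarray | None
    time: float


class TrajectoryEnsemble:
    """Ordered frames over a fixed atom set.

    In-memory container; :func:`exthmmm.io.iter_trajectory` provides a
    streaming path for long on-disk trajectories with the same Frame
    records.
    """

    def __init__(self, topology: MolecularSystem,
                 coordinates: np.ndarray,
                 time: np.ndarray,
                 box: np.ndarray | None = None) -> None:
        self.topology = topology
        self.coordinates = np.asarray(coordinates, dtype=np.float64)
        self.time = np.asarray(time, dtype=np.float64)
        if self.coordinates.ndim != 3 or \
                self.coordinates.shape[1] != topology.n_atoms:
            raise ValueError("coordinates must be (n_frames, n_atoms, 3)")
        if len(self.time) != len(self.coordinates):
            raise ValueError("time and coordinates length mismatch")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("frame times must be strictly increasing")
        if box is None:
            self.box = None
        else:
            box = np.asarray(box, dtype=np.float64)
            if box.ndim == 1:
                box = np.tile(box, (len(self.time), 1))
            self.box = box

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def frame(self, i: int) -> Frame:
        return Frame(
            coordinates=self.coordinates[i],
            box=None if self.box is None else self.box[i],
            time=float(self.time[i]),
        )

    def window(self, t_lo: float, t_hi: float) -> "TrajectoryEnsemble":
        """Frames with t in the closed interval [t_lo, t_hi] (ns)."""
        mask = (self.time >= t_lo) & (self.time <= t_hi)
        if not mask.any():
            raise ValueError(
                f"no frames in window [{t_lo}, {t_hi}] ns "
                f"(trajectory spans {self.time[0]}-{self.time[-1]} ns)"
            )
        return TrajectoryEnsemble(
            self.topology,
            self.coordinates[mask],
            self.time[mask],
            None if self.box is None else self.box[mask],
        )


@dataclass(frozen=True)
class SelectionSpec:
    """A named atom selection: inclusive residue ranges + atom-name filter."""

    name: str
    residue_ranges: tuple[tuple[int, int], ...]
    atom_names: tuple[str, ...] | None = None

    def __init__(self, name: str,
                 residue_ranges: Iterable[Iterable[int]],
                 atom_names: Iterable[str] | None = None) -> None:
        ranges = tuple(tuple(int(v) for v in r) for r in residue_ranges)
        if not ranges:
            raise ValueError(f"selection '{name}': no residue ranges")
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(
                    f"selection '{name}': bad range ({lo}, {hi})"
                )
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "residue_ranges", ranges)
        object.__setattr__(
            self, "atom_names",
            None if atom_names is None else tuple(atom_names),
        )

    def to_dict(self) -> dict:
        d = {"name": self.name,
             "ranges": [list(r) for r in self.residue_ranges]}
        if self.atom_names is not None:
            d["atoms"] = list(self.atom_names)
        return d

    @staticmethod
    def from_dict(d: Mapping) -> "SelectionSpec":
        return SelectionSpec(d["name"], d["ranges"], d.get("atoms"))


def resolve_selection(system: MolecularSystem,
                      spec: SelectionSpec) -> np.ndarray:
    """Atom indices matching the spec, ascending; error if empty."""
    resnum = system.residue_number
    mask = np.zeros(system.n_atoms, dtype=bool)
    for lo, hi in spec.residue_ranges:
        mask |= (resnum >= lo) & (resnum <= hi)
    if spec.atom_names is not None:
        mask &= np.isin(system.atom_name.astype(str),
                        np.asarray(spec.atom_names, dtype=str))
    idx = np.flatnonzero(mask).astype(np.int64)
    if idx.size == 0:
        raise ValueError(
            f"selection '{spec.name}' resolves to zero atoms "
            f"(ranges {list(spec.residue_ranges)}, "
            f"atoms {spec.atom_names})"
        )
    return idx


# The mature-FVa numbering of the default selections (model residues
# 29-2224 of UniProt P12259): C1 = 1879-2033, C2 = 2038-2193, A2 = 320-655,
# C1-C2 linker at 2037.  A1 and A3 boundaries must come from user config.
DEFAULT_C1 = SelectionSpec("C1", [(1879, 2033)], ["CA"])
DEFAULT_C2 = SelectionSpec("C2", [(2038, 2193)], ["CA"])
DEFAULT_A2 = SelectionSpec("A2", [(320, 655)], ["CA"])


@dataclass
class DomainDefinitions:
    """Domain label -> selection, plus the hinge and axis-proxy residues.

    ``kick_order`` is the residue order of the kick dihedral; the default
    (2186, 2127, 2026, 1967) puts the two axis-proxy residues closest to
    the C1-C2 interface in the middle.
    """

    domains: dict[str, SelectionSpec] = field(default_factory=lambda: {
        "C1": DEFAULT_C1, "C2": DEFAULT_C2, "A2": DEFAULT_A2,
    })
    linker_residue: int = 2037
    kick_order: tuple[int, int, int, int] = (2186, 2127, 2026, 1967)

    def require(self, label: str) -> SelectionSpec:
        if label not in self.domains:
            raise KeyError(
                f"domain '{label}' is not defined; available: "
                f"{sorted(self.domains)} (A1/A3 boundaries must be supplied "
                f"via configuration)"
            )
        return self.domains[label]

    def to_dict(self) -> dict:
        return {
            "domains": {k: v.to_dict() for k, v in self.domains.items()},
            "linker_residue": self.linker_residue,
            "kick_order": list(self.kick_order),
        }

    @staticmethod
    def from_dict(d: Mapping) -> "DomainDefinitions":
        dd = DomainDefinitions()
        if "domains" in d:
            doms = {}
            for k, v in d["domains"].items():
                if "name" not in v:
                    v = dict(v, name=k)
                doms[k] = SelectionSpec.from_dict(v)
            dd.domains = {**dd.domains, **doms}
        if "linker_residue" in d:
            dd.linker_residue = int(d["linker_residue"])
        if "kick_order" in d:
            dd.kick_order = tuple(int(v) for v in d["kick_order"])
        return dd


# ---------------------------------------------------------------------------
# geometry primitives


def rotation_about_axis(axis: np.ndarray, angle_degrees: float) -> np.ndarray:
    """3x3 proper rotation by angle_degrees about the given axis
    (right-hand rule)."""
    axis = np.asarray(axis, dtype=np.float64)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("zero-length rotation axis")
    u = axis / n
    t = np.radians(angle_degrees)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal proper rotation taking direction a onto direction b."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cannot align zero-length vector")
    a, b = a / na, b / nb
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, 180.0)
    angle = np.degrees(np.arctan2(np.linalg.norm(v), c))
    return rotation_about_axis(v, angle)


def centroid(coordinates: np.ndarray,
             indices: Sequence[int] | None = None,
             weights: np.ndarray | None = None) -> np.ndarray:
    """Unweighted (or weighted) mean position of the selected atoms.

    The standard orientation metrics run on Cα-only selections, where the
    unweighted centroid equals the center of mass; a ``weights`` array
    (e.g. masses) turns this into a proper center of mass for mixed
    selections.
    """
    coords = np.asarray(coordinates, dtype=np.float64)
    if indices is not None:
        idx = np.asarray(indices, dtype=np.int64)
        if idx.size == 0:
            raise ValueError("centroid of empty selection")
        coords = coords[idx]
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("centroid needs at least one atom")
    if weights is None:
        return coords.mean(axis=0)
    w = np.asarray(weights, dtype=np.float64)
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b between rays b->a and b->c, in [0, 180] degrees."""
    u = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    v = np.asarray(c, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle_deg: zero-length ray at vertex")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_deg(p1: np.ndarray, p2: np.ndarray,
                 p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed dihedral of four points, IUPAC convention, in (-180, 180].

    cis (p1 and p4 eclipsed) is 0, trans is 180; positive sense is a
    right-hand rotation about p2->p3.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=np.float64)
                      for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0:
        raise ValueError("dihedral_deg: coincident middle points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0:
        raise ValueError("dihedral_deg: degenerate (collinear) geometry")
    m1 = np.cross(n1, b2 / nb2)
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = -float(np.degrees(np.arctan2(y, x)))
    # map the torsion onto the half-open interval (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return ang
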