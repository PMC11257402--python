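"""extHMMM membrane-patch construction and initial protein placement.

The patch is a two-leaflet bed of short-tailed (dioctanoyl, 8:0/8:0)
PC/PS lipids sandwiching a slab of 1,1-dichloroethane (DCLE), mirrored
about the membrane center plane z = 0.  Lipid lateral packing is set by
the relative area per lipid (rAPL), a percentage of the experimental
reference areas (68.3 A^2 for POPC, 60.4 A^2 for POPS).  Lipid internal
geometry is deliberately schematic — idealized extended chains at fixed
bead spacing — because the patch feeds geometry analysis and restraint
export, not force-field simulation.

Protein placement reproduces the canonical initial pose for spontaneous
binding runs: long axis along the membrane normal, discoidin domains
facing the membrane, and a ~1 nm gap between the mean upper-leaflet
phosphorus plane and the closest alpha-carbon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import (
    DomainDefinitions,
    MolecularSystem,
    centroid,
    resolve_selection,
    rotation_aligning,
)

__all__ = [
    "ExtHMMMParameters",
    "LeafletLayout",
    "composition_counts",
    "build_leaflet",
    "build_patch",
    "place_protein",
    "export_restraint_definition",
    "load_restraint_definition",
    "RESTRAINT_EXPRESSION",
]

RESTRAINT_EXPRESSION = "k*max(0,|z-z0|-rfb)^2"

# Schematic single-lipid geometry (Angstrom).  Eight tail beads per chain
# at 1.25 A z-spacing span the dioctanoyl tail length; the phosphate sits
# at the tail top and the choline/serine nitrogen 1.5 A further out.
TAIL_BEADS = 8
TAIL_SPACING = 1.25
N_ABOVE_P = 1.5
DCLE_HALF_EXTENT = 2.0  # molecule radius used to keep all atoms in-slab


@dataclass(frozen=True)
class ExtHMMMParameters:
    """extHMMM build parameters.

    Restraint well: center ``z0`` (nm), half-width ``rfb`` (nm), force
    constant ``k`` (kJ mol^-1 nm^-2).  Composition: PC/PS mole fractions
    (4:1 by default).  ``rapl`` is the relative area per lipid in percent
    of the reference areas ``apl_pc``/``apl_ps`` (A^2 per lipid).
    ``dcle_density`` is the solvent number density in molecules/nm^3.
    """

    z0: float = 0.0
    rfb: float = 1.05
    k: float = 10.0
    pc_fraction: float = 0.8
    ps_fraction: float = 0.2
    rapl: float = 110.0
    apl_pc: float = 68.3
    apl_ps: float = 60.4
    dcle_density: float = 8.0

    def __post_init__(self) -> None:
        if abs(self.pc_fraction + self.ps_fraction - 1.0) > 1e-9:
            raise ValueError("lipid fractions must sum to 1")
        if self.rapl <= 0:
            raise ValueError("rAPL must be positive")
        if self.rfb <= 0:
            raise ValueError("rfb must be positive")
        if self.k < 0:
            raise ValueError("k must be non-negative")

    @property
    def rfb_angstrom(self) -> float:
        return self.rfb * 10.0


@dataclass
class LeafletLayout:
    """2D lipid anchor layout of one leaflet."""

    positions: np.ndarray          # (n, 2) x,y anchors, A
    species: np.ndarray            # 'PC' | 'PS' per site
    side: str                      # 'upper' | 'lower'
    box_lengths: tuple[float, float]

    @property
    def n_lipids(self) -> int:
        return len(self.species)

    @property
    def box_area(self) -> float:
        return self.box_lengths[0] * self.box_lengths[1]


def composition_counts(n_lipids: int, params: ExtHMMMParameters
                       ) -> tuple[int, int]:
    """(n_PC, n_PS) by largest-remainder rounding of the mole fractions."""
    import warnings

    exact = np.array([params.pc_fraction, params.ps_fraction]) * n_lipids
    base = np.floor(exact).astype(int)
    rem = exact - base
    short = n_lipids - base.sum()
    for i in np.argsort(-rem)[:short]:
        base[i] += 1
    n_pc, n_ps = int(base[0]), int(base[1])
    if (params.pc_fraction > 0 and n_pc == 0) or \
            (params.ps_fraction > 0 and n_ps == 0):
        warnings.warn(
            f"composition rounds to zero lipids of one species at "
            f"n={n_lipids}", stacklevel=2,
        )
    return n_pc, n_ps


def build_leaflet(n_lipids: int, params: ExtHMMMParameters, side: str,
                  seed: int) -> LeafletLayout:
    """Lay out one leaflet on a jittered square grid.

    The box area is exactly (n_PC*apl_PC + n_PS*apl_PS) * rAPL/100;
    species are assigned to grid sites by a seeded shuffle.
    """
    if n_lipids < 1:
        raise ValueError("need at least one lipid")
    if side not in ("upper", "lower"):
        raise ValueError("side must be 'upper' or 'lower'")
    n_pc, n_ps = composition_counts(n_lipids, params)
    area = (n_pc * params.apl_pc + n_ps * params.apl_ps) * params.rapl / 100.0
    lx = ly = float(np.sqrt(area))

    nx = int(np.ceil(np.sqrt(n_lipids)))
    ny = int(np.ceil(n_lipids / nx))
    sx, sy = lx / nx, ly / ny
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    sites = np.column_stack([
        (ii.ravel() + 0.5) * sx - lx / 2.0,
        (jj.ravel() + 0.5) * sy - ly / 2.0,
    ])[:n_lipids]

    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.1, 0.1, size=(n_lipids, 2)) * np.array([sx, sy])
    species = np.array(["PC"] * n_pc + ["PS"] * n_ps, dtype=object)
    rng.shuffle(species)
    return LeafletLayout(sites + jitter, species, side, (lx, ly))


def _lipid_atoms(anchor_xy: np.ndarray, species: str, side: str,
                 rfb_angstrom: float) -> tuple[list, np.ndarray]:
    """Schematic lipid: N and P headgroup atoms plus two 8-bead tails,
    tails pointing toward z = 0."""
    sign = 1.0 if side == "upper" else -1.0
    z_p = rfb_angstrom + TAIL_BEADS * TAIL_SPACING
    names, elements, coords = [], [], []
    x, y = anchor_xy
    names.append("N"); elements.append("N")
    coords.append([x, y, sign * (z_p + N_ABOVE_P)])
    names.append("P"); elements.append("P")
    coords.append([x, y, sign * z_p])
    for chain, dx in ((2, -0.8), (3, 0.8)):
        for b in range(1, TAIL_BEADS + 1):
            names.append(f"C{chain}{b}")
            elements.append("C")
            coords.append([x + dx, y, sign * (z_p - b * TAIL_SPACING)])
    resname = "D8PC" if species == "PC" else "D8PS"
    meta = [(nm, resname, "MEMB", el) for nm, el in zip(names, elements)]
    return meta, np.asarray(coords)


def _dcle_atoms(center: np.ndarray, rng: np.random.Generator
                ) -> tuple[list, np.ndarray]:
    """1,1-dichloroethane as four heavy-atom beads in a random
    orientation: C1 (the chlorinated carbon), two Cl, and the methyl C2."""
    local = np.array([
        [0.0, 0.0, 0.0],       # C1
        [1.45, 0.9, 0.0],      # CL1
        [-1.45, 0.9, 0.0],     # CL2
        [0.0, -1.5, 0.0],      # C2
    ])
    # random proper rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    coords = local @ q.T + center
    meta = [("C1", "DCLE", "DCLE", "C"), ("CL1", "DCLE", "DCLE", "CL"),
            ("CL2", "DCLE", "DCLE", "CL"), ("C2", "DCLE", "DCLE", "C")]
    return meta, coords


def build_patch(params: ExtHMMMParameters, n_lipids_per_leaflet: int,
                seed: int) -> MolecularSystem:
    """Build the two-leaflet PC/PS + DCLE patch, centered at z = 0.

    Leaflets are mirror images in composition; DCLE molecules fill the
    slab |z| <= rfb uniformly at ``params.dcle_density``.
    """
    if n_lipids_per_leaflet < 1:
        raise ValueError("patch needs at least one lipid per leaflet")
    rng = np.random.default_rng(seed)
    s_upper, s_lower, s_dcle = rng.integers(0, 2**31 - 1, size=3)
    upper = build_leaflet(n_lipids_per_leaflet, params, "upper", int(s_upper))
    lower = build_leaflet(n_lipids_per_leaflet, params, "lower", int(s_lower))

    names, resnames, segids, elements, resnums, coords = [], [], [], [], [], []
    resnum = 0
    for layout in (upper, lower):
        for i in range(layout.n_lipids):
            resnum += 1
            meta, xyz = _lipid_atoms(layout.positions[i],
                                     str(layout.species[i]), layout.side,
                                     params.rfb_angstrom)
            for (nm, rn, seg, el), _ in zip(meta, xyz):
                names.append(nm); resnames.append(rn)
                segids.append(seg); elements.append(el)
                resnums.append(resnum)
            coords.append(xyz)

    lx, ly = upper.box_lengths
    slab_half = params.rfb_angstrom
    vol_nm3 = lx * ly * 2.0 * slab_half / 1000.0
    n_dcle = max(1, int(round(params.dcle_density * vol_nm3)))
    dcle_rng = np.random.default_rng(int(s_dcle))
    for _ in range(n_dcle):
        resnum += 1
        center = np.array([
            dcle_rng.uniform(-lx / 2, lx / 2),
            dcle_rng.uniform(-ly / 2, ly / 2),
            dcle_rng.uniform(-(slab_half - DCLE_HALF_EXTENT),
                             slab_half - DCLE_HALF_EXTENT),
        ])
        meta, xyz = _dcle_atoms(center, dcle_rng)
        for (nm, rn, seg, el), _ in zip(meta, xyz):
            names.append(nm); resnames.append(rn)
            segids.append(seg); elements.append(el)
            resnums.append(resnum)
        coords.append(xyz)

    z_top = params.rfb_angstrom + TAIL_BEADS * TAIL_SPACING + N_ABOVE_P
    box = np.array([lx, ly, 2.0 * (z_top + 20.0)])
    return MolecularSystem(
        atom_name=np.array(names, dtype=object),
        residue_number=np.array(resnums),
        residue_name=np.array(resnames, dtype=object),
        segment_id=np.array(segids, dtype=object),
        element=np.array(elements, dtype=object),
        coordinates=np.vstack(coords),
        box=box,
    )


def upper_phosphate_plane(patch: MolecularSystem) -> float:
    """Mean z of upper-leaflet (z > 0) lipid P atoms, in Angstrom."""
    mask = (patch.atom_name.astype(str) == "P") & (patch.coordinates[:, 2] > 0)
    if not mask.any():
        raise ValueError("patch has no upper-leaflet P atoms")
    return float(patch.coordinates[mask, 2].mean())


def place_protein(patch: MolecularSystem, protein: MolecularSystem,
                  domain_defs: DomainDefinitions | None = None,
                  gap_nm: float = 1.0) -> MolecularSystem:
    """Orient and position the protein in the initial binding pose.

    The long-axis proxy (C1∪C2 Cα centroid -> A2 Cα centroid) is aligned
    with +z so the discoidin domains face the membrane, the protein is
    centered laterally over the patch, and it is raised until the lowest
    Cα sits ``gap_nm`` above the mean upper-leaflet phosphorus plane.
    Returns patch + protein as one system (patch box kept).
    """
    dd = domain_defs or DomainDefinitions()
    c1 = resolve_selection(protein, dd.require("C1"))
    c2 = resolve_selection(protein, dd.require("C2"))
    a2 = resolve_selection(protein, dd.require("A2"))
    c1c2 = centroid(protein.coordinates, np.concatenate([c1, c2]))
    a2c = centroid(protein.coordinates, a2)
    axis = a2c - c1c2
    if np.linalg.norm(axis) < 1e-9:
        raise ValueError("degenerate long-axis proxy")

    rot = rotation_aligning(axis, np.array([0.0, 0.0, 1.0]))
    pivot = centroid(protein.coordinates)
    coords = (protein.coordinates - pivot) @ rot.T + pivot

    z_surface = upper_phosphate_plane(patch)
    ca_mask = protein.atom_name.astype(str) == "CA"
    if not ca_mask.any():
        raise ValueError("protein has no CA atoms")
    gap = gap_nm * 10.0
    dz = (z_surface + gap) - coords[ca_mask, 2].min()
    coords = coords + np.array([0.0, 0.0, dz])
    # center laterally over the patch (which is built centered on x=y=0)
    xy_shift = -coords[ca_mask, :2].mean(axis=0)
    coords = coords + np.array([xy_shift[0], xy_shift[1], 0.0])

    placed = protein.with_coordinates(coords)
    return MolecularSystem.concatenate([patch, placed], box=patch.box)


def export_restraint_definition(params: ExtHMMMParameters,
                                system: MolecularSystem,
                                path: str | Path,
                                dcle_atom_name: str = "C1") -> dict:
    """Write the engine-agnostic flat-bottom restraint spec as JSON.

    One restrained atom per DCLE molecule (default: the chlorinated
    carbon ``C1``); parameters stay in the nm / kJ-mol units in which
    they are defined.
    """
    mask = (system.residue_name.astype(str) == "DCLE") & \
           (system.atom_name.astype(str) == dcle_atom_name)
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise ValueError(
            f"no DCLE atoms named '{dcle_atom_name}' to restrain"
        )
    record = {
        "expression": RESTRAINT_EXPRESSION,
        "z0": params.z0,
        "rfb": params.rfb,
        "k": params.k,
        "units": {"z0": "nm", "rfb": "nm", "k": "kJ/mol/nm^2"},
        "applies_to": [int(i) for i in indices],
        "summary": (
            f"flat-bottom well on z of {indices.size} DCLE atoms "
            f"('{dcle_atom_name}'): zero for |z-{params.z0}| <= "
            f"{params.rfb} nm, harmonic (k={params.k} kJ/mol/nm^2) outside"
        ),
    }
    Path(path).write_text(json.dumps(record, indent=1))
    return record


def load_restraint_definition(path: str | Path) -> dict:
    record = json.loads(Path(path).read_text())
    for key in ("expression", "z0", "rfb", "k", "applies_to"):
        if key not in record:
            raise ValueError(f"restraint file missing '{key}'")
    return record
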