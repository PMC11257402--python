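"""Synthetic fixtures: toy multi-domain proteins, membrane beds, and
trajectories with planted observable values.

The toy protein is a Cα-only caricature of a heavy-chain + dual
discoidin-domain architecture, numbered so the default
:class:`~exthmmm.core.DomainDefinitions` resolve unchanged (A2
320-655, C1 1879-2033, linker 2037, C2 2038-2193, plus A1/A3 blocks).
Each domain is a rigid, seeded cloud of pseudo-Cα atoms; per frame, the
skeleton (linker position, domain centroids, axis-proxy atoms) is
constructed analytically so that the scissors angle φ, kick dihedral θ
and molecular tilt α take their scheduled values *exactly*, before
optional Gaussian coordinate noise.  Ground truth is emitted alongside
every trajectory.

This is a model of the analysis contract, not of factor Va chemistry:
bead-scale lipids, a static membrane bed, and single-bead probe
residues stand in for the real system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .builder import ExtHMMMParameters, build_leaflet
from .core import MolecularSystem, TrajectoryEnsemble, rotation_about_axis

__all__ = [
    "ToyProteinLayout",
    "ProbeSchedule",
    "FixtureSpec",
    "make_toy_fva",
    "make_membrane_bed",
    "make_trajectory",
    "write_fixture",
]

Y = np.array([0.0, 1.0, 0.0])
Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class ToyProteinLayout:
    """Residue blocks and skeleton geometry of the toy protein (A)."""

    a1_range: tuple[int, int] = (29, 303)
    a2_range: tuple[int, int] = (320, 655)
    a3_range: tuple[int, int] = (1546, 1877)
    c1_range: tuple[int, int] = (1879, 2033)
    c2_range: tuple[int, int] = (2038, 2193)
    linker_residue: int = 2037
    c1_proxies: tuple[int, int] = (2026, 1967)   # near-interface, outer
    c2_proxies: tuple[int, int] = (2127, 2186)   # near-interface, outer
    hinge_arm: float = 30.0       # linker -> domain centroid, A
    a2_height: float = 50.0       # C1C2 centroid -> A2 centroid, A
    proxy_axis_offset: float = 15.0   # centroid -> near proxy along axis
    proxy_perp_arm: float = 35.0      # near proxy -> outer proxy, perp
    blob_sigma: float = 5.0       # Gaussian cloud scale per domain


def _cloud(rng: np.random.Generator, n: int, sigma: float,
           fixed: dict[int, np.ndarray] | None = None) -> np.ndarray:
    """n zero-mean offsets; entries in ``fixed`` (index -> offset) are
    pinned and the remaining points are shifted to keep the mean zero."""
    offs = rng.normal(scale=sigma, size=(n, 3))
    if fixed:
        free = np.array([i for i in range(n) if i not in fixed])
        pinned_sum = np.sum([v for v in fixed.values()], axis=0)
        offs[free] -= (offs[free].sum(axis=0) + pinned_sum) / free.size
        for i, v in fixed.items():
            offs[i] = v
    else:
        offs -= offs.mean(axis=0)
    return offs


class _ToyProtein:
    """Precomputed per-domain offset clouds; realizes coordinates for a
    given (φ, θ) and rigid pose."""

    def __init__(self, layout: ToyProteinLayout, seed: int) -> None:
        self.layout = layout
        rng = np.random.default_rng(seed)
        lo, hi = layout.c1_range
        self.c1_residues = list(range(lo, hi + 1))
        lo, hi = layout.c2_range
        self.c2_residues = list(range(lo, hi + 1))
        c = layout.proxy_axis_offset
        g = layout.proxy_perp_arm
        # offsets are coefficients in each domain's orthonormal triad
        i_near1 = self.c1_residues.index(layout.c1_proxies[0])
        i_out1 = self.c1_residues.index(layout.c1_proxies[1])
        self.c1_offsets = _cloud(
            rng, len(self.c1_residues), layout.blob_sigma,
            {i_near1: np.array([c, 0.0, 0.0]),
             i_out1: np.array([c, g, 0.0])},
        )
        i_near2 = self.c2_residues.index(layout.c2_proxies[0])
        i_out2 = self.c2_residues.index(layout.c2_proxies[1])
        self.c2_offsets = _cloud(
            rng, len(self.c2_residues), layout.blob_sigma,
            {i_near2: np.array([c, 0.0, 0.0]),
             i_out2: np.array([c, g, 0.0])},
        )
        self.other_residues = {}
        self.other_offsets = {}
        for label, (lo, hi) in (("A1", layout.a1_range),
                                ("A2", layout.a2_range),
                                ("A3", layout.a3_range)):
            self.other_residues[label] = list(range(lo, hi + 1))
            self.other_offsets[label] = _cloud(
                rng, hi - lo + 1, layout.blob_sigma)

        self.residues = (
            self.other_residues["A1"] + self.other_residues["A2"]
            + self.other_residues["A3"] + self.c1_residues
            + [layout.linker_residue] + self.c2_residues
        )
        self.n_atoms = len(self.residues)

    def skeleton(self, phi: float, theta: float) -> dict[str, np.ndarray]:
        """Analytic skeleton in the canonical pose: linker at the
        origin, scissors plane = x-z, bisector along -z, A2 up."""
        lay = self.layout
        half = np.radians(phi / 2.0)
        u1 = np.array([np.sin(half), 0.0, -np.cos(half)])
        u2 = np.array([-np.sin(half), 0.0, -np.cos(half)])
        c1c = lay.hinge_arm * u1
        c2c = lay.hinge_arm * u2
        n1, n2 = len(self.c1_residues), len(self.c2_residues)
        c1c2 = (n1 * c1c + n2 * c2c) / (n1 + n2)
        a2c = c1c2 + lay.a2_height * Z
        a1c = a2c + np.array([30.0, 10.0, 5.0])
        a3c = c1c2 + np.array([-28.0, 12.0, 20.0])

        c = lay.proxy_axis_offset
        m = c2c - c1c
        m = m / np.linalg.norm(m)
        p3 = c1c + c * m                       # near-interface C1 proxy
        p4 = p3 + lay.proxy_perp_arm * Y       # outer C1 proxy
        m2 = c2c - p3
        m2 = m2 / np.linalg.norm(m2)
        p2 = c2c + c * m2                      # near-interface C2 proxy
        u = p3 - p2
        u = u / np.linalg.norm(u)
        e2 = rotation_about_axis(u, -theta) @ Y
        p1 = p2 + lay.proxy_perp_arm * e2      # outer C2 proxy
        return {
            "C1c": c1c, "C2c": c2c, "C1C2c": c1c2, "A2c": a2c,
            "A1c": a1c, "A3c": a3c, "linker": np.zeros(3),
            "p1": p1, "p2": p2, "p3": p3, "p4": p4,
            "c1_triad": np.column_stack([m, Y, np.cross(m, Y)]),
            "c2_triad": np.column_stack([m2, e2, np.cross(m2, e2)]),
        }

    def coordinates(self, phi: float, theta: float) -> np.ndarray:
        """All Cα positions in the canonical pose (residue order as in
        ``self.residues``)."""
        sk = self.skeleton(phi, theta)
        lay = self.layout
        blocks = []
        for label, center in (("A1", sk["A1c"]), ("A2", sk["A2c"]),
                              ("A3", sk["A3c"])):
            blocks.append(center + self.other_offsets[label])
        blocks.append(sk["C1c"] + self.c1_offsets @ sk["c1_triad"].T)
        blocks.append(sk["linker"][None, :])
        blocks.append(sk["C2c"] + self.c2_offsets @ sk["c2_triad"].T)
        return np.vstack(blocks)

    def system(self, coordinates: np.ndarray) -> MolecularSystem:
        n = self.n_atoms
        return MolecularSystem(
            atom_name=np.array(["CA"] * n, dtype=object),
            residue_number=np.array(self.residues),
            residue_name=np.array(["ALA"] * n, dtype=object),
            segment_id=np.array(["PROT"] * n, dtype=object),
            element=np.array(["C"] * n, dtype=object),
            coordinates=coordinates,
        )


def make_toy_fva(layout: ToyProteinLayout = ToyProteinLayout(),
                 seed: int = 0, phi: float = 120.0, theta: float = 0.0
                 ) -> MolecularSystem:
    """Reference toy protein in the canonical upright pose with the
    given built-in scissors and kick angles."""
    lo1, hi1 = layout.c1_range
    lo2, hi2 = layout.c2_range
    for res in layout.c1_proxies:
        if not lo1 <= res <= hi1:
            raise ValueError(f"C1 axis proxy {res} outside {layout.c1_range}")
    for res in layout.c2_proxies:
        if not lo2 <= res <= hi2:
            raise ValueError(f"C2 axis proxy {res} outside {layout.c2_range}")
    toy = _ToyProtein(layout, seed)
    return toy.system(toy.coordinates(phi, theta))


# ---------------------------------------------------------------------------
# membrane bed


@dataclass(frozen=True)
class MembraneBedSpec:
    n_lipids_per_leaflet: int = 64
    pc_fraction: float = 0.8
    apl_pc: float = 68.3
    apl_ps: float = 60.4
    rapl: float = 100.0
    p_plane_z: float = 19.0       # A, planted |z| of the P planes
    n_above_p: float = 1.5        # N sits this far outside P
    tail_below_p: float = 5.0     # single schematic tail bead
    dcle_half_width: float = 10.5  # A, uniform slab half-width
    n_dcle: int = 600


def make_membrane_bed(spec: MembraneBedSpec = MembraneBedSpec(),
                      seed: int = 0) -> MolecularSystem:
    """Two-leaflet bead membrane with exactly planted P/N planes and a
    uniform single-bead DCLE slab."""
    if spec.n_lipids_per_leaflet < 2:
        raise ValueError("bed needs at least 2 lipids per leaflet")
    params = ExtHMMMParameters(
        pc_fraction=spec.pc_fraction, ps_fraction=1.0 - spec.pc_fraction,
        rapl=spec.rapl, apl_pc=spec.apl_pc, apl_ps=spec.apl_ps,
    )
    rng = np.random.default_rng(seed)
    s_up, s_lo = rng.integers(0, 2**31 - 1, size=2)
    names, resnames, segids, elements, resnums, coords = \
        [], [], [], [], [], []
    resnum = 0
    layouts = {
        "upper": build_leaflet(spec.n_lipids_per_leaflet, params,
                               "upper", int(s_up)),
        "lower": build_leaflet(spec.n_lipids_per_leaflet, params,
                               "lower", int(s_lo)),
    }
    for side, layout in layouts.items():
        sign = 1.0 if side == "upper" else -1.0
        for i in range(layout.n_lipids):
            resnum += 1
            x, y = layout.positions[i]
            resname = "D8PC" if layout.species[i] == "PC" else "D8PS"
            for nm, el, z in (("N", "N", spec.p_plane_z + spec.n_above_p),
                              ("P", "P", spec.p_plane_z),
                              ("C1", "C", spec.p_plane_z - spec.tail_below_p)):
                names.append(nm); elements.append(el)
                resnames.append(resname); segids.append("MEMB")
                resnums.append(resnum)
                coords.append([x, y, sign * z])
    lx, ly = layouts["upper"].box_lengths
    # DCLE beads are placed in mirror pairs (+z / -z) so the slab
    # centroid is exactly at z = 0, the plane analyses re-center on
    half_sites = [
        [rng.uniform(-lx / 2, lx / 2), rng.uniform(-ly / 2, ly / 2),
         rng.uniform(0.0, spec.dcle_half_width)]
        for _ in range(spec.n_dcle // 2)
    ]
    dcle_sites = half_sites + [[x, y, -z] for x, y, z in half_sites]
    if spec.n_dcle % 2:
        dcle_sites.append([0.0, 0.0, 0.0])
    for site in dcle_sites:
        resnum += 1
        names.append("C1"); elements.append("C")
        resnames.append("DCLE"); segids.append("DCLE")
        resnums.append(resnum)
        coords.append(site)
    z_top = spec.p_plane_z + spec.n_above_p
    return MolecularSystem(
        atom_name=np.array(names, dtype=object),
        residue_number=np.array(resnums),
        residue_name=np.array(resnames, dtype=object),
        segment_id=np.array(segids, dtype=object),
        element=np.array(elements, dtype=object),
        coordinates=np.asarray(coords),
        box=np.array([lx, ly, 2.0 * (z_top + 25.0)]),
    )


# ---------------------------------------------------------------------------
# trajectories


@dataclass(frozen=True)
class ProbeSchedule:
    """A single-bead probe residue with planted behaviour.

    mode 'contacts': in the frames listed per lipid class the probe is
    parked 2 A above the P atom of a 'safe' lipid of that class (one
    whose nearest other-class lipid cannot also be within the cutoff);
    in all other frames it is parked far above the membrane.
    mode 'random_lipid': each frame the probe visits a uniformly chosen
    safe upper-leaflet lipid, so contact classes follow the bed
    stoichiometry.
    mode 'depth': the probe follows an absolute z schedule at fixed xy.
    """

    residue_number: int
    mode: str = "contacts"
    contact_frames: tuple[tuple[str, tuple[int, ...]], ...] = ()
    z: tuple[float, ...] | None = None
    xy: tuple[float, float] = (0.0, 0.0)
    name: str = "CA"

    def contact_map(self) -> dict[str, set[int]]:
        return {cls: set(frames) for cls, frames in self.contact_frames}


@dataclass
class FixtureSpec:
    """Scheduled trajectory fixture; scalar schedules are constant."""

    seed: int = 0
    n_frames: int = 100
    dt: float = 1.0            # ns
    t0: float = 0.0
    noise_sigma: float = 0.0   # A, iid Gaussian per coordinate
    include_protein: bool = True
    include_membrane: bool = False
    layout: ToyProteinLayout = field(default_factory=ToyProteinLayout)
    membrane: MembraneBedSpec = field(default_factory=MembraneBedSpec)
    tilt: float | tuple = 0.0
    phi: float | tuple = 120.0
    theta: float | tuple = 0.0
    z_c1c2: float | tuple = 60.0   # z of the C1∪C2 centroid, A
    probes: tuple[ProbeSchedule, ...] = ()

    def schedule(self, value, name: str) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float64)
        if arr.ndim == 0:
            return np.full(self.n_frames, float(arr))
        if arr.shape != (self.n_frames,):
            raise ValueError(
                f"schedule '{name}' has length {arr.shape}, expected "
                f"{self.n_frames}"
            )
        return arr


def fixture_spec_from_dict(d: dict) -> FixtureSpec:
    """Build a FixtureSpec from a plain (e.g. YAML-loaded) mapping."""
    d = dict(d)
    if "layout" in d:
        d["layout"] = ToyProteinLayout(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d["layout"].items()
        })
    if "membrane" in d:
        d["membrane"] = MembraneBedSpec(**d["membrane"])
    if "probes" in d:
        probes = []
        for p in d["probes"]:
            p = dict(p)
            if "contact_frames" in p:
                p["contact_frames"] = tuple(
                    (cls, tuple(frames))
                    for cls, frames in p["contact_frames"].items()
                )
            if "z" in p and p["z"] is not None:
                p["z"] = tuple(p["z"])
            if "xy" in p:
                p["xy"] = tuple(p["xy"])
            probes.append(ProbeSchedule(**p))
        d["probes"] = tuple(probes)
    for key in ("tilt", "phi", "theta", "z_c1c2"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return FixtureSpec(**d)


PROBE_ABOVE_P = 2.0     # A, probe height above the target lipid P atom
PROBE_PARK_Z = 60.0     # A, park height in non-contact frames
CONTACT_CUTOFF = 5.0


def _safe_lipids(bed: MolecularSystem) -> dict[str, list[int]]:
    """Upper-leaflet lipid residue numbers per class whose nearest
    other-class lipid anchor is too far to co-trigger a contact."""
    names = bed.atom_name.astype(str)
    resnames = bed.residue_name.astype(str)
    p_mask = (names == "P") & (bed.coordinates[:, 2] > 0)
    p_idx = np.flatnonzero(p_mask)
    xy = bed.coordinates[p_idx, :2]
    cls = np.where(resnames[p_idx] == "D8PC", "PC", "PS")
    # other-class atoms can reach within the cutoff only if their anchor
    # is laterally closer than sqrt(cutoff^2 - min dz^2); use a margin
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    safe: dict[str, list[int]] = {"PC": [], "PS": []}
    limit = CONTACT_CUTOFF + 1.0
    for i in range(len(p_idx)):
        other = cls != cls[i]
        if not other.any() or np.sqrt(d2[i][other].min()) > limit:
            safe[cls[i]].append(int(bed.residue_number[p_idx[i]]))
    return safe


def make_trajectory(spec: FixtureSpec
                    ) -> tuple[TrajectoryEnsemble, pd.DataFrame]:
    """Realize the scheduled fixture.

    Returns the trajectory and a ground-truth table with one row per
    frame holding the *planted* values: tilt/phi/theta, per-domain
    z-separations, the A1-C2 centroid distance, and per-probe contact
    classes and heights.
    """
    n = spec.n_frames
    rng = np.random.default_rng(spec.seed)
    s_protein, s_bed, s_noise, s_probe = rng.integers(0, 2**31 - 1, size=4)

    systems = []
    toy = None
    if spec.include_protein:
        toy = _ToyProtein(spec.layout, int(s_protein))
        systems.append(toy.system(toy.coordinates(120.0, 0.0)))
    bed = None
    if spec.include_membrane or spec.probes:
        bed = make_membrane_bed(spec.membrane, int(s_bed))
        systems.append(bed)
    probe_systems = []
    for probe in spec.probes:
        probe_systems.append(MolecularSystem(
            atom_name=np.array([probe.name], dtype=object),
            residue_number=np.array([probe.residue_number]),
            residue_name=np.array(["PRB"], dtype=object),
            segment_id=np.array(["PROB"], dtype=object),
            element=np.array(["C"], dtype=object),
            coordinates=np.zeros((1, 3)),
        ))
    systems.extend(probe_systems)
    if not systems:
        raise ValueError("fixture contains no atoms")
    box = bed.box if bed is not None else np.array([200.0, 200.0, 200.0])
    topology = MolecularSystem.concatenate(systems, box=box)

    tilt_s = spec.schedule(spec.tilt, "tilt")
    phi_s = spec.schedule(spec.phi, "phi")
    theta_s = spec.schedule(spec.theta, "theta")
    z_s = spec.schedule(spec.z_c1c2, "z_c1c2")

    # probe targets
    safe = _safe_lipids(bed) if bed is not None else {}
    probe_rng = np.random.default_rng(int(s_probe))
    p_by_res = {}
    if bed is not None:
        names = bed.atom_name.astype(str)
        for i in np.flatnonzero(names == "P"):
            p_by_res[int(bed.residue_number[i])] = bed.coordinates[i]

    def probe_position(probe: ProbeSchedule, f: int) -> tuple[np.ndarray,
                                                              str | None]:
        if probe.mode == "depth":
            if probe.z is None:
                raise ValueError(
                    f"probe {probe.residue_number}: depth mode needs z"
                )
            z = spec.schedule(probe.z, f"probe {probe.residue_number} z")
            return np.array([*probe.xy, z[f]]), None
        if probe.mode == "random_lipid":
            # a uniform draw over safe lipids follows the bed
            # stoichiometry up to the few excluded boundary cases
            pool = safe["PC"] + safe["PS"]
            res = pool[int(probe_rng.integers(len(pool)))]
            cls = "PC" if res in set(safe["PC"]) else "PS"
            pos = p_by_res[res] + np.array([0, 0, PROBE_ABOVE_P])
            return pos, cls
        if probe.mode == "contacts":
            for cls, frames in probe.contact_map().items():
                if f in frames:
                    if not safe.get(cls):
                        raise ValueError(f"no safe {cls} lipids in bed")
                    res = safe[cls][probe.residue_number % len(safe[cls])]
                    pos = p_by_res[res] + np.array([0, 0, PROBE_ABOVE_P])
                    return pos, cls
            return np.array([*probe.xy, PROBE_PARK_Z]), None
        raise ValueError(f"unknown probe mode '{probe.mode}'")

    # consistency: a depth probe cannot also plant contacts
    for probe in spec.probes:
        if probe.mode == "depth" and probe.contact_frames:
            z = spec.schedule(probe.z, "z")
            for cls, frames in probe.contact_map().items():
                for f in frames:
                    if abs(z[f] - spec.membrane.p_plane_z) > CONTACT_CUTOFF:
                        raise ValueError(
                            f"probe {probe.residue_number}: contact "
                            f"planted at frame {f} but scheduled "
                            f"{abs(z[f] - spec.membrane.p_plane_z):.1f} A "
                            f"from the membrane surface"
                        )

    noise_rng = np.random.default_rng(int(s_noise))
    frames = np.empty((n, topology.n_atoms, 3))
    truth_rows = []
    for f in range(n):
        parts = []
        row = {"frame": f, "time": spec.t0 + f * spec.dt}
        if toy is not None:
            coords = toy.coordinates(phi_s[f], theta_s[f])
            sk = toy.skeleton(phi_s[f], theta_s[f])
            pivot = sk["C1C2c"]
            R = rotation_about_axis([1.0, 0.0, 0.0], tilt_s[f])
            coords = (coords - pivot) @ R.T + pivot
            shift = np.array([0.0, 0.0, z_s[f]]) - pivot
            coords = coords + shift
            parts.append(coords)
            row.update({"alpha": tilt_s[f], "phi": phi_s[f],
                        "theta": theta_s[f]})
            for label in ("A1c", "A2c", "A3c", "C1c", "C2c"):
                center = (sk[label] - pivot) @ R.T + pivot + shift
                row[f"z_{label[:-1]}"] = abs(center[2])
            a1 = (sk["A1c"] - pivot) @ R.T + pivot + shift
            c2 = (sk["C2c"] - pivot) @ R.T + pivot + shift
            row["dist_A1_C2"] = float(np.linalg.norm(a1 - c2))
        if bed is not None:
            parts.append(bed.coordinates)
        for probe in spec.probes:
            pos, cls = probe_position(probe, f)
            parts.append(pos[None, :])
            row[f"probe{probe.residue_number}_class"] = cls or ""
            row[f"probe{probe.residue_number}_z"] = pos[2]
        frames[f] = np.vstack(parts)
        truth_rows.append(row)
    if spec.noise_sigma > 0:
        frames += noise_rng.normal(scale=spec.noise_sigma,
                                   size=frames.shape)
    time = spec.t0 + spec.dt * np.arange(n)
    traj = TrajectoryEnsemble(topology, frames, time, box)
    return traj, pd.DataFrame(truth_rows)


def write_fixture(spec: FixtureSpec, out_dir: str | Path,
                  trajectory_format: str = "dcd"
                  ) -> tuple[Path, Path, Path]:
    """Write topology PDB, binary trajectory, and ground_truth.csv."""
    from .io import write_trajectory

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj, truth = make_trajectory(spec)
    top_path = out / "fixture.pdb"
    traj_path = out / f"fixture.{trajectory_format}"
    write_trajectory(traj, top_path, traj_path)
    truth_path = out / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    return top_path, traj_path, truth_path
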