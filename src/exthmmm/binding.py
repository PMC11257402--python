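"""Orientation and domain-organization observables.

Per-frame metrics of a multi-domain peripheral membrane protein over a
mimetic bilayer:

* domain z-separation — distance of a domain's Cα centroid from the
  membrane center plane z = 0;
* molecular tilt α — angle of the long-axis proxy (C1∪C2 Cα centroid to
  A2 Cα centroid) against the membrane normal.  The reported tilt is 0°
  for the upright bound pose (discoidin domains down, A2 up); the
  complementary "raw" angle of the A2→C1C2 binding direction against +z
  (180° when upright) is emitted alongside;
* scissors angle φ — angle at the C1-C2 linker Cα between the C1 and C2
  domain centroids;
* kick angle θ — signed dihedral of the C2 and C1 axis-proxy Cα pairs,
  capturing out-of-plane reorientation of C2 relative to C1;
* basin gating of the (φ, θ) plane and percentile-bootstrap confidence
  intervals for per-basin statistics.

Frames are re-centered before any z-based metric so that the membrane
center (DCLE centroid z, or mean lipid P z when no DCLE is present)
defines z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import (
    DomainDefinitions,
    Frame,
    MolecularSystem,
    TrajectoryEnsemble,
    angle_deg,
    centroid,
    dihedral_deg,
    resolve_selection,
)

__all__ = [
    "BasinGate",
    "BootstrapCI",
    "membrane_center_z",
    "domain_z_separation",
    "tilt_angle",
    "scissors_angle",
    "kick_angle",
    "assign_basin",
    "bootstrap_ci",
    "angle_series",
    "BOUND_WINDOW_NS",
    "ILLUSTRATIVE_BASINS",
]

# Membrane-bound analysis window (ns), closed on both ends.
BOUND_WINDOW_NS = (100.0, 500.0)


def membrane_center_z(frame: Frame, topology: MolecularSystem) -> float:
    """z of the membrane center: DCLE centroid z if DCLE is present,
    else the mean z of lipid P atoms; error if neither exists."""
    resname = topology.residue_name.astype(str)
    dcle = resname == "DCLE"
    if dcle.any():
        return float(frame.coordinates[dcle, 2].mean())
    p_atoms = topology.atom_name.astype(str) == "P"
    if p_atoms.any():
        return float(frame.coordinates[p_atoms, 2].mean())
    raise ValueError("no DCLE or lipid P atoms to define the membrane center")


def _ca_index(topology: MolecularSystem, residue: int) -> int:
    mask = (topology.residue_number == residue) & \
           (topology.atom_name.astype(str) == "CA")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"no CA atom for residue {residue}")
    return int(idx[0])


def domain_z_separation(frame: Frame, topology: MolecularSystem,
                        domain, z_center: float = 0.0) -> float:
    """|z of the domain Cα centroid| relative to the membrane center."""
    idx = resolve_selection(topology, domain)
    c = centroid(frame.coordinates, idx)
    return float(abs(c[2] - z_center))


def tilt_angle(frame: Frame, topology: MolecularSystem,
               domain_defs: DomainDefinitions | None = None,
               folded: bool = True) -> float:
    """Molecular tilt in degrees.

    ``folded=True`` (default) reports 0° for the upright pose in which
    the C1C2→A2 axis points along +z (A2 up, discoidin domains toward
    the membrane); ``folded=False`` returns the raw angle of the
    A2→C1C2 binding direction against +z (180° when upright).
    """
    dd = domain_defs or DomainDefinitions()
    c1 = resolve_selection(topology, dd.require("C1"))
    c2 = resolve_selection(topology, dd.require("C2"))
    a2 = resolve_selection(topology, dd.require("A2"))
    c1c2 = centroid(frame.coordinates, np.concatenate([c1, c2]))
    a2c = centroid(frame.coordinates, a2)
    v = a2c - c1c2
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("degenerate (zero-length) long-axis proxy")
    up = float(np.degrees(np.arccos(np.clip(v[2] / n, -1.0, 1.0))))
    return up if folded else 180.0 - up


def scissors_angle(frame: Frame, topology: MolecularSystem,
                   domain_defs: DomainDefinitions | None = None) -> float:
    """Angle at the C1-C2 linker Cα between the C1 and C2 Cα centroids."""
    dd = domain_defs or DomainDefinitions()
    c1 = centroid(frame.coordinates,
                  resolve_selection(topology, dd.require("C1")))
    c2 = centroid(frame.coordinates,
                  resolve_selection(topology, dd.require("C2")))
    hinge = frame.coordinates[_ca_index(topology, dd.linker_residue)]
    return angle_deg(c1, hinge, c2)


def kick_angle(frame: Frame, topology: MolecularSystem,
               domain_defs: DomainDefinitions | None = None) -> float:
    """Signed dihedral over the axis-proxy Cα residues (degrees,
    (-180, 180]); residue order is ``domain_defs.kick_order``."""
    dd = domain_defs or DomainDefinitions()
    pts = [frame.coordinates[_ca_index(topology, r)] for r in dd.kick_order]
    return dihedral_deg(*pts)


@dataclass(frozen=True)
class BasinGate:
    """Rectangular gate in the (φ, θ) plane."""

    label: str
    phi_range: tuple[float, float]
    theta_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.phi_range[0] < self.phi_range[1] and
                self.theta_range[0] < self.theta_range[1]):
            raise ValueError(f"gate '{self.label}': lo must be < hi")

    def contains(self, phi: float, theta: float) -> bool:
        return (self.phi_range[0] <= phi <= self.phi_range[1] and
                self.theta_range[0] <= theta <= self.theta_range[1])


# Illustrative gates only: published φ-θ landscapes name the basins but
# not their boundaries, so quantitative per-basin work must supply gates
# from configuration.
ILLUSTRATIVE_BASINS = (
    BasinGate("Xtal", (115.0, 135.0), (-30.0, 10.0)),
    BasinGate("m1", (110.0, 130.0), (10.0, 50.0)),
    BasinGate("m2", (85.0, 110.0), (-40.0, 10.0)),
)


def assign_basin(phi: float, theta: float,
                 gates: Sequence[BasinGate]) -> str:
    """Label of the first gate containing (φ, θ); 'unassigned' if none.
    Priority order is the gate list order (documented tie-break)."""
    for gate in gates:
        if gate.contains(phi, theta):
            return gate.label
    return "unassigned"


@dataclass(frozen=True)
class BootstrapCI:
    estimate: float
    lower: float
    upper: float
    level: float = 90.0
    n_resamples: int = 1000

    def __post_init__(self) -> None:
        if not (self.lower <= self.estimate + 1e-12 and
                self.estimate <= self.upper + 1e-12):
            raise ValueError("CI bounds must bracket the point estimate")


def bootstrap_ci(samples, statistic: Callable = np.mean,
                 n_resamples: int = 1000, level: float = 90.0,
                 seed: int | None = None) -> BootstrapCI:
    """Seeded percentile bootstrap CI (default 90%, 1,000 resamples
    with replacement)."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 2:
        raise ValueError("bootstrap needs at least 2 samples")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_resamples, x.size))
    stats = np.apply_along_axis(statistic, 1, x[idx]) \
        if statistic is not np.mean else x[idx].mean(axis=1)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(stats, [alpha, 100.0 - alpha])
    est = float(statistic(x))
    return BootstrapCI(est, float(min(lo, est)), float(max(hi, est)),
                       level, n_resamples)


def angle_series(traj: TrajectoryEnsemble,
                 domain_defs: DomainDefinitions | None = None,
                 gates: Sequence[BasinGate] = (),
                 bound_window: tuple[float, float] | None = None,
                 recenter: bool | None = None) -> pd.DataFrame:
    """Per-frame table of time, tilt (folded + raw), φ, θ, per-domain
    z-separation and basin label.

    ``bound_window=(lo, hi)`` restricts analysis to the closed time
    interval [lo, hi] ns (the membrane-bound convention is
    :data:`BOUND_WINDOW_NS`).  ``recenter`` shifts each frame so the
    membrane center sits at z = 0; by default it is on exactly when the
    topology contains membrane atoms (DCLE or lipid P).
    """
    dd = domain_defs or DomainDefinitions()
    if bound_window is not None:
        traj = traj.window(*bound_window)
    top = traj.topology
    if recenter is None:
        resname = top.residue_name.astype(str)
        recenter = bool((resname == "DCLE").any() or
                        (top.atom_name.astype(str) == "P").any())

    rows = []
    for frame in traj:
        zc = membrane_center_z(frame, top) if recenter else 0.0
        if zc != 0.0:
            frame = Frame(frame.coordinates - np.array([0, 0, zc]),
                          frame.box, frame.time)
        alpha = tilt_angle(frame, top, dd)
        phi = scissors_angle(frame, top, dd)
        theta = kick_angle(frame, top, dd)
        row = {
            "time": frame.time,
            "alpha": alpha,
            "alpha_raw": 180.0 - alpha,
            "phi": phi,
            "theta": theta,
            "basin": assign_basin(phi, theta, gates) if gates else
                     "unassigned",
        }
        for label, spec in dd.domains.items():
            row[f"z_{label}"] = domain_z_separation(frame, top, spec)
        rows.append(row)
    return pd.DataFrame(rows)
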