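"""Residue-lipid contact frequencies, PS-vs-PC preference, and
inter-domain contacts.

A residue is "in contact" with a lipid class in a frame when any of its
atoms lies within the cutoff (5.0 A, inclusive) of any atom of a lipid
of that class; frequencies are the fraction of analysed frames with at
least one contact.  Preference is freq_PS - freq_PC, the signed
deviation from the equal-frequency diagonal.  Inter-domain contacts
count Cα-Cα pairs within 10.0 A.

Minimum-image periodicity is applied in the membrane plane (x, y) only
by default: the protein binds one leaflet, so wrapping z would create
spurious contacts with the far leaflet's image.  Full 3D wrapping is
available via ``periodic="xyz"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DomainDefinitions,
    Frame,
    MolecularSystem,
    TrajectoryEnsemble,
    centroid,
    resolve_selection,
)

__all__ = [
    "DEFAULT_LIPID_CLASSES",
    "min_distance",
    "residue_lipid_contact",
    "contact_frequency_table",
    "preference_scores",
    "interdomain_contacts",
    "interdomain_distance",
    "map_scores_to_structure",
]

CONTACT_CUTOFF = 5.0        # A, residue-lipid and residue-residue
INTERDOMAIN_CUTOFF = 10.0   # A, Cα-Cα domain-domain contact points
NEUTRAL_BAND = 0.02         # |preference| below this is displayed neutral

DEFAULT_LIPID_CLASSES = {
    "PC": ("D8PC", "POPC", "DOPC", "DPPC", "DVPC"),
    "PS": ("D8PS", "POPS", "DOPS", "DVPS"),
}


def _pair_deltas(a: np.ndarray, b: np.ndarray, box, periodic: str
                 ) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    if periodic:
        if box is None:
            raise ValueError("periodic minimum-image requires a box")
        dims = {"x": 0, "y": 1, "z": 2}
        for ax in periodic:
            i = dims[ax]
            d[..., i] -= box[i] * np.round(d[..., i] / box[i])
    return d


def min_distance(a: np.ndarray, b: np.ndarray, box=None,
                 periodic: str = "xy") -> float:
    """Minimum inter-atomic distance between two coordinate sets (A),
    with minimum-image wrapping on the axes named in ``periodic``."""
    d = _pair_deltas(np.asarray(a, float), np.asarray(b, float),
                     box, periodic)
    return float(np.sqrt((d ** 2).sum(axis=-1).min()))


def residue_lipid_contact(frame: Frame, residue_indices, lipid_indices,
                          cutoff: float = CONTACT_CUTOFF,
                          periodic: str = "xy") -> bool:
    """True iff any residue atom is within ``cutoff`` (inclusive) of any
    lipid atom."""
    ri = np.asarray(residue_indices, dtype=np.int64)
    li = np.asarray(lipid_indices, dtype=np.int64)
    if ri.size == 0 or li.size == 0:
        raise ValueError("empty selection in contact test")
    dmin = min_distance(frame.coordinates[ri], frame.coordinates[li],
                        frame.box, periodic)
    return dmin <= cutoff


def _residue_groups(topology: MolecularSystem, indices: np.ndarray
                    ) -> dict[int, np.ndarray]:
    groups: dict[int, list] = {}
    for i in indices:
        groups.setdefault(int(topology.residue_number[i]), []).append(i)
    return {r: np.asarray(v, dtype=np.int64) for r, v in groups.items()}


def _lipid_class_indices(topology: MolecularSystem,
                         lipid_classes: dict | None) -> dict[str, np.ndarray]:
    classes = {k: tuple(v) for k, v in
               (lipid_classes or DEFAULT_LIPID_CLASSES).items()}
    resnames = topology.residue_name.astype(str)
    known = {rn for names in classes.values() for rn in names}
    lipid_like = np.isin(resnames,
                         [rn for rn in np.unique(resnames) if rn in known])
    out = {}
    for cls, names in classes.items():
        idx = np.flatnonzero(np.isin(resnames, names))
        out[cls] = idx
    # any membrane-segment residue name outside the map is an error
    memb = np.flatnonzero(
        (topology.segment_id.astype(str) == "MEMB") & ~lipid_like
    )
    if memb.size:
        unmapped = sorted(set(resnames[memb]))
        raise ValueError(
            f"unmapped lipid residue names: {unmapped}; extend the "
            f"lipid-class map"
        )
    return out


def _domain_label(residue: int, domain_defs: DomainDefinitions | None) -> str:
    if domain_defs is None:
        return ""
    for label, spec in domain_defs.domains.items():
        for lo, hi in spec.residue_ranges:
            if lo <= residue <= hi:
                return label
    return ""


def contact_frequency_table(traj: TrajectoryEnsemble,
                            protein_residue_indices,
                            lipid_classes: dict | None = None,
                            cutoff: float = CONTACT_CUTOFF,
                            periodic: str = "xy",
                            bound_window: tuple[float, float] | None = None,
                            domain_defs: DomainDefinitions | None = None,
                            ) -> pd.DataFrame:
    """Per-residue contact frequency with each lipid headgroup class.

    Returns a DataFrame with columns residue_number, domain, freq_PC,
    freq_PS (one ``freq_<class>`` column per class) and n_frames.
    """
    if bound_window is not None:
        traj = traj.window(*bound_window)
    top = traj.topology
    groups = _residue_groups(top,
                             np.asarray(protein_residue_indices, np.int64))
    class_idx = _lipid_class_indices(top, lipid_classes)
    counts = {r: {c: 0 for c in class_idx} for r in groups}
    for frame in traj:
        for resnum, ridx in groups.items():
            rcoords = frame.coordinates[ridx]
            for cls, lidx in class_idx.items():
                if lidx.size == 0:
                    continue
                d = min_distance(rcoords, frame.coordinates[lidx],
                                 frame.box, periodic)
                if d <= cutoff:
                    counts[resnum][cls] += 1
    n = traj.n_frames
    rows = []
    for resnum in sorted(groups):
        row = {"residue_number": resnum,
               "domain": _domain_label(resnum, domain_defs),
               "n_frames": n}
        for cls in class_idx:
            row[f"freq_{cls}"] = counts[resnum][cls] / n
        rows.append(row)
    return pd.DataFrame(rows)


def preference_scores(table: pd.DataFrame,
                      neutral_band: float = NEUTRAL_BAND) -> pd.DataFrame:
    """PS-vs-PC preference per residue, ranked by descending preference.

    preference = freq_PS - freq_PC in [-1, 1]; classification is for
    display only (|preference| < ``neutral_band`` -> 'neutral').
    """
    if table.empty:
        raise ValueError("empty contact table")
    out = table.copy()
    out["preference"] = out["freq_PS"] - out["freq_PC"]
    out["classification"] = np.where(
        np.abs(out["preference"]) < neutral_band, "neutral",
        np.where(out["preference"] > 0, "PS-preferring", "PC-preferring"),
    )
    return out.sort_values("preference", ascending=False,
                           kind="mergesort").reset_index(drop=True)


def interdomain_contacts(frame: Frame, topology: MolecularSystem,
                         domain_a, domain_b,
                         cutoff: float = INTERDOMAIN_CUTOFF) -> int:
    """Number of Cα-Cα residue pairs of two domains within ``cutoff``."""
    ia = resolve_selection(topology, domain_a)
    ib = resolve_selection(topology, domain_b)
    d = _pair_deltas(frame.coordinates[ia], frame.coordinates[ib],
                     None, "")
    dist = np.sqrt((d ** 2).sum(axis=-1))
    return int((dist <= cutoff).sum())


def interdomain_distance(frame: Frame, topology: MolecularSystem,
                         domain_a, domain_b) -> float:
    """Distance between the Cα centroids of two domains (A)."""
    ca = centroid(frame.coordinates, resolve_selection(topology, domain_a))
    cb = centroid(frame.coordinates, resolve_selection(topology, domain_b))
    return float(np.linalg.norm(ca - cb))


def map_scores_to_structure(scores: dict[int, float],
                            system: MolecularSystem,
                            path,
                            score_range: tuple[float, float] = (0.0, 1.0),
                            sentinel: float = -1.0) -> np.ndarray:
    """Write a PDB with per-residue scores in the temperature-factor
    column, linearly scaled from ``score_range`` onto 0-100; residues
    without a score get ``sentinel``.  Returns the B-factor array."""
    from .io import write_pdb

    if not scores:
        raise ValueError("no scores to map")
    lo, hi = score_range
    bfac = np.full(system.n_atoms, sentinel)
    for resnum, score in scores.items():
        if not (lo <= score <= hi):
            raise ValueError(
                f"score {score} for residue {resnum} outside declared "
                f"range {score_range}"
            )
        mask = system.residue_number == resnum
        bfac[mask] = (score - lo) / (hi - lo) * 100.0
    write_pdb(system, path, tempfactors=bfac)
    return bfac
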