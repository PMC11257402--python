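"""Spike insertion depths and membrane reference planes.

Heights are z coordinates relative to the membrane center plane z = 0
(frames are assumed centered; :func:`exthmmm.binding.membrane_center_z`
provides the offset otherwise).  Reference planes are the mean z of
lipid headgroup N and P atoms of a leaflet, and the width of the
organic (DCLE) core is summarized as the full width at half maximum of
its z density histogram, interpolated linearly between the bins that
cross half-peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Frame, MolecularSystem, TrajectoryEnsemble

__all__ = [
    "residue_height",
    "mean_plane",
    "fwhm_from_samples",
    "dcle_density_fwhm",
    "spike_profiles",
    "InsertionProfile",
]

FWHM_BIN_WIDTH = 0.5  # A


def _residue_atom_indices(topology: MolecularSystem, residue: int,
                          mode: str) -> np.ndarray:
    mask = topology.residue_number == residue
    if not mask.any():
        raise ValueError(f"residue {residue} absent from topology")
    names = topology.atom_name.astype(str)
    elements = topology.element.astype(str)
    if mode == "ca":
        mask &= names == "CA"
    elif mode == "sidechain":
        backbone = np.isin(names, ["N", "CA", "C", "O", "H", "HA"])
        side = mask & ~backbone
        if side.any():
            mask = side
    elif mode == "heavy":
        mask &= elements != "H"
    else:
        raise ValueError(f"unknown height mode '{mode}'")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"residue {residue}: no atoms for mode '{mode}'")
    return idx


def residue_height(frame: Frame, topology: MolecularSystem, residue: int,
                   mode: str = "heavy", z_center: float = 0.0) -> float:
    """Signed z of the residue's atom centroid relative to the membrane
    center (default: heavy-atom centroid of the whole residue)."""
    idx = _residue_atom_indices(topology, residue, mode)
    return float(frame.coordinates[idx, 2].mean() - z_center)


def _leaflet_mask(topology: MolecularSystem, frame: Frame,
                  leaflet: str) -> np.ndarray:
    """Per-atom leaflet membership of lipid residues, assigned by the
    sign of each lipid's P-atom z in this frame."""
    names = topology.atom_name.astype(str)
    resnum = topology.residue_number
    p_idx = np.flatnonzero(names == "P")
    if p_idx.size == 0:
        raise ValueError("no lipid P atoms in topology")
    sign = 1.0 if leaflet == "upper" else -1.0
    wanted = p_idx[np.sign(frame.coordinates[p_idx, 2]) == sign]
    return np.isin(resnum, resnum[wanted])


def mean_plane(traj: TrajectoryEnsemble, atom_name: str = "P",
               leaflet: str = "upper",
               bound_window: tuple[float, float] | None = None) -> float:
    """Mean z (A) of the named headgroup atoms of one leaflet, pooled
    over the (optionally windowed) trajectory."""
    if leaflet not in ("upper", "lower"):
        raise ValueError("leaflet must be 'upper' or 'lower'")
    if bound_window is not None:
        traj = traj.window(*bound_window)
    top = traj.topology
    name_mask = top.atom_name.astype(str) == atom_name
    if not name_mask.any():
        raise ValueError(f"no atoms named '{atom_name}' in topology")
    zs = []
    for frame in traj:
        mask = name_mask & _leaflet_mask(top, frame, leaflet)
        if mask.any():
            zs.append(frame.coordinates[mask, 2])
    if not zs:
        raise ValueError(f"no '{atom_name}' atoms in the {leaflet} leaflet")
    return float(np.concatenate(zs).mean())


def fwhm_from_samples(z_samples: np.ndarray,
                      bin_width: float = FWHM_BIN_WIDTH) -> float:
    """FWHM (A) of the histogram of z samples.

    The raw histogram is used (no kernel smoothing); the half-maximum
    crossings are located by linear interpolation between adjacent bin
    centers, which keeps the estimator fully reproducible.
    """
    z = np.asarray(z_samples, dtype=np.float64)
    if z.size < 100:
        raise ValueError(f"need >= 100 z samples for FWHM, got {z.size}")
    lo, hi = z.min(), z.max()
    nbins = max(1, int(np.ceil((hi - lo) / bin_width)))
    counts, edges = np.histogram(z, bins=nbins, range=(lo, lo + nbins * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = counts.max()
    half = peak / 2.0

    above = counts >= half
    i_first = int(np.argmax(above))
    i_last = int(len(counts) - 1 - np.argmax(above[::-1]))
    # left crossing
    if i_first == 0:
        left = centers[0] - bin_width / 2.0
    else:
        c0, c1 = counts[i_first - 1], counts[i_first]
        left = centers[i_first - 1] + \
            (half - c0) / (c1 - c0) * (centers[i_first] - centers[i_first - 1])
    # right crossing
    if i_last == len(counts) - 1:
        right = centers[-1] + bin_width / 2.0
    else:
        c0, c1 = counts[i_last], counts[i_last + 1]
        right = centers[i_last] + \
            (half - c0) / (c1 - c0) * (centers[i_last + 1] - centers[i_last])
    return float(right - left)


def dcle_density_fwhm(traj: TrajectoryEnsemble,
                      bin_width: float = FWHM_BIN_WIDTH,
                      bound_window: tuple[float, float] | None = None
                      ) -> float:
    """FWHM of the DCLE z-density pooled over the trajectory window."""
    if bound_window is not None:
        traj = traj.window(*bound_window)
    mask = traj.topology.residue_name.astype(str) == "DCLE"
    if not mask.any():
        raise ValueError("no DCLE atoms in topology")
    z = traj.coordinates[:, mask, 2].ravel()
    return fwhm_from_samples(z, bin_width)


@dataclass
class InsertionProfile:
    """Pooled spike-residue height samples plus membrane references."""

    samples: pd.DataFrame      # spike, residue_number, time, height
    summary: pd.DataFrame      # per residue: median, 95% band, n
    p_plane: float             # <P> of the upper leaflet, A
    n_plane: float             # <N> of the upper leaflet, A
    dcle_fwhm: float | None    # A, None when the system has no DCLE


def spike_profiles(traj: TrajectoryEnsemble,
                   spikes: dict[str, list[int]],
                   bound_window: tuple[float, float] | None = None,
                   mode: str = "heavy") -> InsertionProfile:
    """Height distributions for the spike residues, pooled over the
    bound window, with <N>/<P> reference planes and the DCLE FWHM.

    ``spikes`` maps a spike label (e.g. 'C2 spike 1') to its residue
    numbers; memberships are configuration, not inferred.
    """
    if not spikes:
        raise ValueError("no spike definitions supplied")
    if bound_window is not None:
        traj = traj.window(*bound_window)
    top = traj.topology
    rows = []
    for frame in traj:
        for spike, residues in spikes.items():
            for res in residues:
                rows.append({
                    "spike": spike,
                    "residue_number": res,
                    "time": frame.time,
                    "height": residue_height(frame, top, res, mode=mode),
                })
    samples = pd.DataFrame(rows)
    summary = (
        samples.groupby(["spike", "residue_number"])["height"]
        .agg(median="median",
             lo=lambda h: np.percentile(h, 2.5),
             hi=lambda h: np.percentile(h, 97.5),
             n="size")
        .reset_index()
    )
    try:
        fwhm = dcle_density_fwhm(traj)
    except ValueError:
        fwhm = None
    return InsertionProfile(
        samples=samples,
        summary=summary,
        p_plane=mean_plane(traj, "P", "upper"),
        n_plane=mean_plane(traj, "N", "upper"),
        dcle_fwhm=fwhm,
    )
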