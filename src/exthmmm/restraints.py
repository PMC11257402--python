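"""Flat-bottom well restraint on the membrane normal.

The extHMMM organic core (DCLE) is held in a slab around the membrane
center by a flat-bottom harmonic well acting on the z coordinate of one
atom per solvent molecule:

    u(z)  = k * dr^2,   dr = max(0, r - rfb),   r = |z - z0|

with z0 = 0 nm, rfb = 1.05 nm and k = 10 kJ mol^-1 nm^-2 by default.
Inside the slab (|z - z0| <= rfb) the potential is exactly zero, so
solvent dynamics are unperturbed; outside it rises quadratically.  The
potential is C1-continuous at the slab edge.

All functions here work in nm (the natural unit of the restraint
parameters); :func:`nm_to_angstrom` / :func:`angstrom_to_nm` convert
explicitly at the boundary with the Angstrom-based structure model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FlatBottomWell",
    "well_energy",
    "well_force",
    "nm_to_angstrom",
    "angstrom_to_nm",
]

NM_PER_ANGSTROM = 0.1


def nm_to_angstrom(x_nm):
    return np.asarray(x_nm, dtype=np.float64) / NM_PER_ANGSTROM


def angstrom_to_nm(x_angstrom):
    return np.asarray(x_angstrom, dtype=np.float64) * NM_PER_ANGSTROM


@dataclass(frozen=True)
class FlatBottomWell:
    """Flat-bottom well: center z0 (nm), half-width rfb (nm), force
    constant k (kJ mol^-1 nm^-2)."""

    z0: float = 0.0
    rfb: float = 1.05
    k: float = 10.0

    def __post_init__(self) -> None:
        if self.rfb <= 0:
            raise ValueError("rfb must be positive")
        if self.k < 0:
            raise ValueError("k must be non-negative")


def well_energy(z, well: FlatBottomWell = FlatBottomWell()):
    """Restraint energy u(z) in kJ/mol; z in nm (scalar or array)."""
    z = np.asarray(z, dtype=np.float64)
    dr = np.maximum(0.0, np.abs(z - well.z0) - well.rfb)
    u = well.k * dr * dr
    return float(u) if u.ndim == 0 else u

def well_force(z, well: FlatBottomWell = FlatBottomWell()):
    """z-component of the restoring force -du/dz in kJ mol^-1 nm^-1.

    Zero inside the slab, including at the edge |z - z0| = rfb where the
    potential is C1 and both one-sided limits agree.
    """
    z = np.asarray(z, dtype=np.float64)
    disp = z - well.z0
    dr = np.maximum(0.0, np.abs(disp) - well.rfb)
    f = -2.0 * well.k * dr * np.sign(disp)
    return float(f) if f.ndim == 0 else f
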