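"""Data-complete figures for the standard analyses.

These helpers plot exactly what the analysis tables contain — no
styling beyond what makes the data legible, and no attempt to mimic any
particular published figure.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_binding_series",
    "plot_phi_theta_landscape",
    "plot_preference_scatter",
    "plot_insertion_profile",
]


def plot_binding_series(angles: pd.DataFrame, ax=None):
    """Time series of per-domain z-separation and molecular tilt."""
    if ax is None:
        _, ax = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    for col in sorted(c for c in angles.columns if c.startswith("z_")):
        ax[0].plot(angles["time"], angles[col], label=col[2:])
    ax[0].set_ylabel("z-separation (Å)")
    ax[0].legend(fontsize=8)
    ax[1].plot(angles["time"], angles["alpha"], color="k")
    ax[1].set_ylabel("tilt α (°)")
    ax[1].set_xlabel("time (ns)")
    return ax


def plot_phi_theta_landscape(angles: pd.DataFrame, gates=(), ax=None):
    """2D histogram of the scissors-kick plane, with optional gates."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    h = ax.hist2d(angles["phi"], angles["theta"], bins=40, cmap="viridis")
    plt.colorbar(h[3], ax=ax, label="frames")
    for gate in gates:
        lo_p, hi_p = gate.phi_range
        lo_t, hi_t = gate.theta_range
        ax.add_patch(plt.Rectangle((lo_p, lo_t), hi_p - lo_p, hi_t - lo_t,
                                   fill=False, edgecolor="w"))
        ax.annotate(gate.label, (lo_p, hi_t), color="w", fontsize=8)
    ax.set_xlabel("scissors φ (°)")
    ax.set_ylabel("kick θ (°)")
    return ax


def plot_preference_scatter(prefs: pd.DataFrame, loglog: bool = False,
                            ax=None):
    """freq_PC vs freq_PS per residue; the diagonal is no preference."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    sc = ax.scatter(prefs["freq_PC"], prefs["freq_PS"],
                    c=prefs["preference"], cmap="coolwarm_r",
                    vmin=-1, vmax=1, s=18)
    lim = max(prefs["freq_PC"].max(), prefs["freq_PS"].max(), 1e-3)
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    if loglog:
        floor = 1e-3
        ax.set_xscale("log"); ax.set_yscale("log")
        ax.set_xlim(floor, lim * 1.2); ax.set_ylim(floor, lim * 1.2)
    plt.colorbar(sc, ax=ax, label="freq_PS − freq_PC")
    ax.set_xlabel("contact frequency with PC")
    ax.set_ylabel("contact frequency with PS")
    return ax


def plot_insertion_profile(profile, ax=None):
    """Violin plot of spike residue heights with <N>/<P> reference
    planes; annotates the DCLE FWHM when available."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    samples = profile.samples
    residues = (samples[["spike", "residue_number"]]
                .drop_duplicates().itertuples(index=False))
    data, labels = [], []
    for spike, res in residues:
        sel = samples.query("spike == @spike and residue_number == @res")
        data.append(sel["height"].to_numpy())
        labels.append(f"{res}\n{spike}")
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(np.arange(1, len(labels) + 1), labels, fontsize=7)
    ax.axhline(profile.p_plane, color="r", ls="--", lw=0.8, label="<P>")
    ax.axhline(profile.n_plane, color="b", ls="--", lw=0.8, label="<N>")
    ax.axhline(0.0, color="k", lw=0.6)
    if profile.dcle_fwhm is not None:
        ax.annotate(f"DCLE FWHM = {profile.dcle_fwhm:.1f} Å",
                    (0.02, 0.04), xycoords="axes fraction", fontsize=8)
    ax.set_ylabel("height above membrane center (Å)")
    ax.legend(fontsize=8)
    return ax
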