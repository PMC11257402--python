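# Methods

## The extHMMM membrane surrogate

The toolkit models a membrane-mimetic patch as two leaflets of
short-tailed (dioctanoyl, 8:0/8:0) PC and PS lipids over an organic
core of 1,1-dichloroethane (DCLE), mirror-symmetric about the membrane
center plane z = 0. The core is held in a slab by a flat-bottom
harmonic well acting on the z coordinate of one atom per DCLE molecule,

u(z) = k·dr², dr = max(0, r − r_fb), r = |z − z₀|,

with defaults z₀ = 0 nm, r_fb = 1.05 nm, k = 10 kJ mol⁻¹ nm⁻². The
potential is identically zero inside the slab and C¹-continuous at the
edge; the force is −du/dz = −2k·(|z − z₀| − r_fb)·sign(z − z₀) outside
and zero inside, including exactly at |z − z₀| = r_fb where both
one-sided limits agree. The restraint API works in nm (the natural
parameter unit); everything structural is in Å, and conversions are
explicit (`restraints.angstrom_to_nm` / `nm_to_angstrom`), never
implicit.

Which DCLE atom carries the restraint is a user choice; the default is
the chlorinated carbon (atom `C1`), the heaviest carbon of the
molecule, exposed through `export_restraint_definition(...,
dcle_atom_name=...)`. The exported restraint record is engine-agnostic
JSON: the energy expression, the three constants with units, and the
restrained atom indices.

### Patch geometry

Lipid lateral packing is exact bookkeeping: the leaflet box area equals
(n_PC·APL_PC + n_PS·APL_PS)·rAPL/100, with reference areas APL_PC =
68.3 Å² and APL_PS = 60.4 Å² per lipid and rAPL the relative area per
lipid in percent. Species counts come from largest-remainder rounding
of the mole fractions (4:1 PC:PS by default); species are assigned to a
jittered square grid by a seeded shuffle (jitter uniform ±10% of the
grid spacing, to avoid artificial lattice artifacts in contact tests).

Lipid internal geometry is deliberately schematic — headgroup N and P
beads above two idealized extended 8-bead tails at 1.25 Å spacing,
tails pointing at the core — because the builder's outputs feed
geometry analysis and restraint export, not force-field simulation.
The DCLE slab is filled uniformly at 8.0 molecules/nm³ by default
(configurable; the appropriate density is a modelling choice, roughly
liquid-like for the slab volume), with whole molecules kept inside
|z| ≤ r_fb.

### Initial protein placement

`place_protein` reproduces the canonical starting pose for spontaneous
binding runs: the long-axis proxy (C1∪C2 Cα centroid → A2 Cα centroid)
is rotated onto +z so the discoidin domains face the membrane, the
protein is centered laterally, and it is translated so the *lowest* Cα
sits exactly `gap_nm` (default 1.0 nm) above the membrane surface,
defined as the mean z of upper-leaflet P atoms — the conventional
phosphate-plane reference. Placement is idempotent: re-placing an
already-placed protein changes no coordinate beyond numerical noise.

## Orientation and organization observables

All Cα-only "centers of mass" are unweighted centroids (all Cα share a
mass); mass-weighted centroids are available for mixed selections.
Frames are re-centered before any z-based metric so the membrane center
defines z = 0, using the DCLE centroid z, or the mean lipid-P z when no
DCLE is present; protein-only systems are analysed unshifted.

* **Tilt α.** The angle between the C1C2→A2 axis proxy and +z. Two
  conventions exist in the literature (raw axis angle vs its
  supplement); this package *reports* the folded value — 0° for the
  upright bound pose with A2 up — and emits the raw angle of the
  A2→C1C2 "binding direction" against +z (180° when upright) in the
  same table (`alpha` / `alpha_raw`). The folded convention makes
  binding time series start near 0°.
* **Scissors φ.** Angle at the linker Cα (residue 2037) between the C1
  and C2 Cα centroids; in [0°, 180°].
* **Kick θ.** Signed IUPAC dihedral (right-hand rule about the middle
  segment, cis = 0°, range (−180°, 180°]) over the axis-proxy Cα
  residues in the order (2186, 2127, 2026, 1967) — the two proxies
  nearest the C1–C2 interface in the middle, so θ is the rotation of
  C2's axis relative to C1's about the inter-domain direction. The
  order is configurable (`DomainDefinitions.kick_order`) since it is a
  convention, not a law.
* **Basins.** Rectangular gates on the (φ, θ) plane with first-match
  priority. Published basin labels are not accompanied by quantitative
  boundaries, so the shipped gates (`examples/basins_illustrative.yaml`,
  `binding.ILLUSTRATIVE_BASINS`) are explicitly illustrative; per-basin
  statistics require user-supplied gates.
* **Bound window.** Pooled "membrane-bound" statistics use the closed
  interval t ∈ [100, 500] ns; a frame at exactly 100.0 ns is included,
  99.9 ns is not. All other windows in the package are closed-open.
* **Bootstrap.** Percentile bootstrap, 1,000 resamples with
  replacement, 90% level, seeded. At sample size 100 the percentile
  interval for a mean shows the well-known slight undercoverage
  (empirically ≈ 88–90% across seeds).

Domain boundaries C1 = 1879–2033, C2 = 2038–2193, A2 = 320–655 (mature
numbering of a model spanning residues 29–2224 of UniProt P12259) are
built in; A1 and A3 boundaries are not standardized and must be
supplied via configuration (`examples/domains.yaml` shows the ones the
toy protein uses).

## Contacts and preference

A residue contacts a lipid class in a frame when any residue atom is
within 5.0 Å (inclusive) of any atom of a lipid of that class; no atom
subset is imposed. Minimum-image periodicity applies in x,y only by
default: the protein binds one leaflet, and wrapping z would connect it
to the far leaflet's periodic image; full 3D wrapping is available.
Frequencies are (frames with ≥1 contact)/(frames analysed), so tables
are invariant to frame order. Preference is freq_PS − freq_PC ∈ [−1, 1];
the "neutral" classification band (|preference| < 0.02) is display
only — raw values are always emitted. Inter-domain contacts (e.g.
A1–C2) count Cα–Cα pairs within 10.0 Å, non-periodic (intra-protein).
Per-residue scores can be written into the PDB temperature-factor
column scaled 0–100, sentinel −1.0 for unscored residues.

## Insertion depths and membrane references

Residue height is the z of the residue's heavy-atom centroid by default
(Cα-only and sidechain-centroid variants exist), relative to z = 0.
Leaflet membership of a lipid is the sign of its P-atom z in each frame
(robust to rare flip-flop). ⟨N⟩ and ⟨P⟩ are means over all matching
atoms of a leaflet over the window. The DCLE density FWHM uses the raw
z histogram (0.5 Å bins) with linear interpolation between the bin
centers crossing half-maximum — no kernel smoothing, so the estimator
is exactly reproducible; on Gaussian data it converges to 2.355σ within
about one bin width.

## Selection-specific RMSD

`rmsd_series` superposes each frame onto the reference using the
*alignment* selection (least-squares Kabsch fit, equal weights, Cα by
convention, via `scipy.spatial.transform.Rotation.align_vectors`) and
reports the RMSD of the *measurement* selection. Aligning on a rigid
block and measuring another separates internal rearrangement from
whole-body motion; aligning a selection on itself is optimal for it, a
property the tests verify.

## The synthetic fixture generator

Fixtures exist so that every analysis is testable against planted
truth without external data. The toy protein is Cα-only: five rigid
seeded Gaussian clouds (σ = 5 Å) for A1/A2/A3/C1/C2 plus a single
linker atom, numbered so the default selections resolve. Per frame the
skeleton — linker at the origin, domain centroids at 30 Å arms opening
by the scheduled φ in the x–z plane, axis-proxy atoms at 15 Å along and
35 Å perpendicular to the inter-domain axis realizing the scheduled θ
by explicit rotation construction, A2 centroid 50 Å up — is built
analytically, each domain cloud is expressed in a per-frame orthonormal
triad (keeping domains internally rigid), the whole protein is rotated
about x by the scheduled tilt and translated to the scheduled height.
Scheduled observables are therefore *exact* before noise; iid Gaussian
coordinate noise (σ in Å) is added last. The proxy lever arms are
domain-scale (the real discoidin domains are ~40–50 Å long) and keep
angle recovery well-conditioned: at σ = 0.2 Å the recovered
tilt/scissors/kick series match their schedules with RMSE ≈ 0.02°,
0.6°, and 0.7°.

The bead membrane plants exact reference planes (all upper P atoms at
+19 Å, N at +20.5 Å by default) and a uniform DCLE slab of half-width
10.5 Å placed in mirror pairs so the slab centroid is exactly z = 0 —
otherwise re-centering on the DCLE centroid would shift noiseless
fixtures off their planted values. Contact and depth probes are
single-bead residues: contact probes park 2 Å above the P atom of a
"safe" lipid of the planted class (one whose nearest other-class lipid
is laterally too far to co-trigger the 5 Å criterion — safety computed
from realized positions, not assumed), and 60 Å above the membrane
otherwise; depth probes follow an absolute z schedule. Inconsistent
specs (a contact planted while the probe is scheduled far from the
surface) are rejected, not silently fixed.

What fixtures do *not* model: force-field energetics, realistic
dynamics or kinetics, all-atom sidechains, lipid diffusion (the bed is
static), or solvent. Passing recovery tests demonstrates that the
*analysis contract* is honored — the estimators return what was
planted at the stated noise — not that any biological conclusion about
FVa is reproduced at desk scale.

## Problem sizes and determinism

Default test problem sizes are chosen for exhaustive checkability:
patches of 25–100 lipids per leaflet, fixture trajectories of 5–200
frames at ~2,000–9,000 atoms, 100,000-sample FWHM checks, and a
2,000-replicate bootstrap coverage simulation. Every stochastic step —
leaflet shuffling, grid jitter, DCLE placement, cloud generation,
noise, resampling — flows from an explicit integer seed through
`numpy.random.default_rng`; identical specs yield bit-identical
coordinates, and the CLI records a config-hash manifest per run.
Trajectory files are written through MDAnalysis (PDB topology + DCD or
XTC frames) with a JSON sidecar of per-frame times in ns, since binary
trajectory formats do not reliably round-trip absolute times; DCD
round-trips coordinates to float32 (~2·10⁻³ Å here), XTC to its native
10⁻³ nm fixed point.

## Known limitations

* The builder emits schematic structures: no topology/force-field
  files, no solvation, no minimization — running MD is out of scope.
* A1/A3 boundaries, spike memberships and basin gates are user
  configuration by design; defaults cover only what is standardized.
* Contact search is a dense minimum-image computation, adequate for
  fixture- and patch-scale systems; very large systems would want a
  cell list.
* The percentile bootstrap slightly undercovers at n = 100; no
  BCa/studentized correction is applied because the plain percentile
  interval is the documented procedure.
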