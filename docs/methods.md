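# Methods

This note documents the models, algorithms and numerical choices behind
`graphsorb`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is simulated, under which assumptions, and
what the defaults mean.

## Scientific setting

BMP-2 (bone morphogenetic protein 2) is a disulfide-linked homodimeric
growth factor whose osteogenic activity depends on two receptor-binding
epitopes per monomer: the wrist (residues 49–63, type I receptor) and
the knuckle (residues 34, 39, 88, 90, 100, type II receptor).  When the
protein adsorbs onto an implant material such as pyrolytic graphite,
two things decide whether it stays bioactive: how strongly it binds
(adsorption energy), and whether its secondary structure — one
four-turn α-helix and two antiparallel β-sheets per monomer — survives
the encounter.  Nanoscale surface topography changes both.  This
package reproduces, at desk scale, the computational protocol used to
study that question: build a patterned graphite slab, place the dimer
side-on above it, steer it onto the surface, relax, and quantify
energy, conformation and contacts.

## Substrate model

Graphite (001) is generated as stacked honeycomb layers on an
orthorhombic four-atom cell.  With C–C bond length 1.418 Å the
in-plane repeat is (√3·1.418, 3·1.418) = (2.456, 4.254) Å and the
interlayer spacing is 3.348 Å with AB stacking — equivalently, the
conventional half-cell parameters a = 1.228 Å, b = 2.127 Å and a
two-layer c axis of 6.696 Å.  The generated periodic cell is the
largest whole number of repeats that fits the requested extent, so the
slab tiles seamlessly under periodic boundaries.  Substrate atoms are
rigid and uncharged: the surface acts purely through the 12-6
Lennard-Jones potential.

Topographies are exclusions carved into the top of a flat slab:

* linear gratings — rectangular grooves, optionally repeated at a pitch;
* square slots — a square-footprint recess;
* circular slots — a circular cross-section (cylinder along y, or a
  sphere) whose axis sits `depth` Å below the surface.  Depth 0 gives
  an open hemicylindrical/hemispherical groove; sinking the circle
  narrows the mouth and makes the walls overhang, producing a profile
  that can *conform* around an adsorbate.

Removal is strictly-inside, so a zero-size pattern is exactly a no-op
and carving is idempotent.  One practical constraint discovered during
validation: the slab must keep at least a full cutoff depth (12 Å) of
carbon beneath the deepest carved floor, otherwise recessed patterns
are spuriously under-binding simply because the surface below them is
thin.  The default toy slab is therefore ~30 Å thick.

## Energetics

The adsorption energy is the non-bonded protein–substrate energy inside
a 12 Å cutoff (plain truncation, no switching function):

    U_vdw  = Σ 4 ε_ij [ (σ_ij/r_ij)^12 − (σ_ij/r_ij)^6 ]
    U_coul = Σ k_C q_i q_j / r_ij

with the minimum-image convention in the periodic x/y directions.  The
joint graphite parameters are σ_ij = 3.195 Å and a well depth of
0.439 kJ/mol applied to every protein heavy atom by default (per-element
overrides are available).  Parameter listings in the CHARMM tradition
print ε as a negative number; the package stores the well depth as a
positive ε and reports the potential minimum as −0.439 kJ/mol at
r = 2^(1/6)·σ, which is what yields attractive (negative) adsorption
energies.  Graphite carbons carry no partial charge, so the Coulomb
component of the adsorption energy is exactly zero and adsorption is
purely van der Waals.

Neighbour search uses a periodic KD-tree (a cell-list equivalent); the
test suite enforces agreement with an all-pairs double loop to
1e-8 kJ/mol.  Contacts are counted per residue: the number of its atoms
whose minimum-image distance to the nearest substrate atom is ≤ 5 Å.

## Conformation metrics

* **RMSD** is computed against the first frame *without superposition*:
  the substrate fixes a lab frame, and fitting out rigid motion would
  hide exactly the adsorption-driven approach the metric is meant to
  show.  A Kabsch fit is available behind a flag.  A time-averaged
  aggregate (mean of per-frame values) is also offered.
* **Radius of gyration** is the mass-weighted RMS distance to the
  centre of mass, reported in Å (i.e. the square root of the
  mass-weighted second moment).
* **Dihedrals** φ (C(i−1)–N–Cα–C) and ψ (N–Cα–C–N(i+1)) follow the
  IUPAC sign convention; termini and chain breaks (C–N distance > 2 Å)
  yield undefined angles that are flagged, not silently dropped.
* **Ramachandran classification** labels each (φ, ψ) pair favored,
  allowed or disallowed against a coarse polygon map of the canonical
  β, right-handed α and left-handed α basins, shipped as a replaceable
  JSON asset (`graphsorb/data/rama_regions.json`).  The boundaries are
  deliberately simple rectangles: the analyses that depend on them ask
  only "did residues leave the plausible basins", not for
  crystallographic-grade contours.
* **Secondary structure** follows the Kabsch–Sander scheme: amide
  hydrogens are reconstructed geometrically (1.01 Å from N along the
  preceding C=O direction), the electrostatic H-bond energy
  0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol is thresholded
  at −0.5 kcal/mol, α-helices (H) come from consecutive i→i+4 turns,
  3₁₀-helices (G) from i→i+3 turns, and strands (E) from parallel/
  antiparallel bridge rules.  Helix takes priority over strand over
  3₁₀.  Everything else is "other" (turn/bend/coil are not
  sub-classified).  Different assigners (DSSP, STRIDE) disagree by
  about one residue per element boundary; content percentages therefore
  carry an implicit ±1-residue (≈1%) assigner tolerance, and the test
  suite cross-checks against mdtraj's DSSP under exactly that
  tolerance.

## Simulation protocol

The solvated 252k-atom NAMD protocol is emulated at desk scale:

1. **Minimization** — L-BFGS on the mobile atoms (deterministic).
2. **Steered dynamics (SMD)** — a harmonic anchor (k = 167.36
   kJ mol⁻¹ Å⁻², default velocity 0.001 Å/ps at full scale) starts at
   the pulled-set centroid and moves toward the surface; the spring
   force is distributed equally (optionally mass-weighted) over the
   pulled atoms.  The pulling force and accumulated work are logged;
   for a pinned target the logged force is exactly k·v·t, which the
   tests assert to machine precision.
3. **Relaxation** — Langevin dynamics at 310 K.

Integration is BAOAB Langevin, which reduces exactly to velocity Verlet
at zero friction (the NVE limit used for the energy-drift check).
Boundary conditions are periodic in x/y with reflective hard walls in
z.  Substrate atoms never move.  All randomness flows from a single
integer seed; identical seeds give bit-identical trajectories.

The Langevin friction (default γ = 1 ps⁻¹) doubles as an implicit
solvent.  This is the main fidelity gap relative to the full explicit-
water simulation: there is no hydrodynamic drag anisotropy, no
hydration-layer structure, and no dielectric screening beyond the
uncharged substrate making electrostatics moot.  Consequently the
package does not attempt to reproduce the absolute adsorption energies
or absolute Rg of the solvated system, only analytic identities,
internal consistency, and the qualitative pattern ranking.

Desk-scale runs use dt = 2–4 fs (the bead model has no bond faster than
~0.3 ps), pulling at 0.25 Å/ps with per-pattern SMD durations (deeper
topographies need longer pulls, mirroring the protocol's
pattern-dependent durations, e.g. 8 ps for flat vs 96 ps for the square
slot at full scale) and 80 ps of relaxation.  These sizes keep a full
three-condition, five-seed comparison within minutes while leaving the
adsorbed state visibly equilibrated in the energy logs.

## Internal protein models

Two stand-ins for the CHARMM protein are provided:

* an all-backbone geometric model (N, Cα, C, O per residue) used by the
  conformational analyses and built by the fixture generators from
  internal coordinates (NeRF), with exact target dihedrals;
* a bead-spring Cα model for dynamics: harmonic bonds (b₀ = 3.8 Å),
  optional harmonic angles, and a 12-6 pair term between non-bonded
  beads.

The toy homodimer used in the pattern-ranking study is two 24-bead
chains linked by one inter-chain bond (standing in for the Cys78–Cys78
bridge), chain A below chain B.  Its bead–bead pair term is
*attractive* (ε = 3.0 kJ/mol ≈ 1.2 kT at 310 K, σ = 4 Å): this
native-contact cohesion makes the dimer a compact globule that keeps
its shape, as a folded protein does.  The choice matters: a purely
repulsive chain melts into a pancake on flat graphite and trivially
maximizes contact there, inverting the topography ranking.  With a
cohesive globule the geometry works as in the full study — the
conforming circular slot (CS2, a spherical pocket of radius ≈ globule
radius + contact distance) wraps the lower half of the dimer and binds
strongest, the generic square slot adds sidewall contact, and the flat
surface binds least.

What the toy dimer does *not* emulate: sequence-specific residue
chemistry (no charged/polar residues driving particular contacts),
secondary-structure elements inside the globule, and solvent-mediated
forces.  Passing the ranking check therefore shows that the pipeline's
geometry, energetics and dynamics interact correctly — not that a real
BMP-2 would show these magnitudes.

## Replicate statistics

Each condition is run with n paired seeds (default 3 at full scale,
5 in the ranking check).  Pairwise paired t-tests (two-sided) are
reported with raw p-values and Holm-adjusted p-values side by side;
the raw values mirror the original analysis, the adjusted ones guard
the multiple-comparison caveat.  Conditions with identical replicate
vectors give t = 0, p = 1; a constant nonzero shift (zero-variance
difference) is reported as infinitely significant rather than NaN.

## Degenerate inputs and tie-breaks

* Zero-size patterns: exact no-op; pattern depth beyond the slab
  thickness: error.
* LJ/Coulomb at r = 0: error (singularity), not a silent clamp.
* Residues missing backbone atoms: flagged and excluded from dihedral/
  SS analysis, never silently dropped from the model.
* Altloc duplicates in PDB input: highest occupancy wins.
* Minimization never returns a state with higher energy than the input.
* A particle crossing both z walls in one step aborts with advice to
  reduce dt.

## Known limitations

* Implicit solvent only; absolute energies/Rg are not comparable to
  solvated all-atom values.
* The coarse Ramachandran polygons are a classification aid, not a
  validation-grade contour set.
* Secondary-structure content carries the ±1-residue assigner
  tolerance discussed above.
* The bead dimer's cohesion parameter is a single scalar; there is no
  per-residue specificity, so per-residue contact maps from toy runs
  are structural, not chemical, statements.
* Coordinates are stored at PDB precision (float32 container); metric
  cross-checks are exact with respect to the stored coordinates.
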