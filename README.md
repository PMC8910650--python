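# graphsorb

Desk-scale simulation and analysis of protein adsorption on
nanopatterned graphite.

BMP-2 (bone morphogenetic protein 2) is a homodimeric growth factor
used to induce bone regeneration around implants.  Whether it works
after adsorbing onto an implant surface depends on two competing
outcomes: binding strongly enough to stay put, and keeping the
secondary structure of its receptor-binding epitopes (the wrist,
residues 49–63, and the knuckle, residues 34/39/88/90/100) intact.
Nanoscale surface topography — gratings, square slots, circular slots —
shifts that balance.  `graphsorb` is a self-contained pipeline for
studying this at desk scale, aimed at people who want a tested,
reproducible model system rather than a cluster-scale MD campaign:

* **substrate construction** — atomistic graphite (001) slabs
  (orthorhombic honeycomb cell, a = 2.456 Å, b = 4.254 Å, interlayer
  3.348 Å, AB stacking) with parametric carved topographies;
* **protein preparation** — PDB input, physiological protonation tags
  (Lys/Arg +1, Glu/Asp −1, His → neutral HSE), epitope selection,
  rigid side-on placement at an exact 12 Å clearance;
* **energetics** — 12-6 Lennard-Jones adsorption energy
  (σ = 3.195 Å, well depth 0.439 kJ/mol, 12 Å cutoff, periodic x/y)
  with per-residue 5 Å contact counts;
* **dynamics** — energy minimization, constant-velocity steered MD
  (k = 167.36 kJ mol⁻¹ Å⁻²), and Langevin relaxation at 310 K over the
  rigid substrate, with reflective z walls and exact seed determinism;
* **conformation analysis** — RMSD (substrate-fixed frame), radius of
  gyration, φ/ψ dihedrals with Ramachandran classification, and
  DSSP-style secondary-structure content tables;
* **synthetic fixtures** — ideal helices/hairpins built from internal
  coordinates, self-avoiding bead proteins, and a cohesive bead-spring
  homodimer, so every stage is testable without downloading anything.

The model and defaults are documented in [docs/methods.md](docs/methods.md).

## Worked example

Build an ideal 12-residue α-helix and ask for its secondary-structure
content:

```python
from graphsorb.synthetic import make_ideal_helix
from graphsorb.conformation import assign_secondary_structure, ss_content_table

helix = make_ideal_helix(12)            # phi = -57, psi = -47 exactly
print(ss_content_table(assign_secondary_structure(helix)))
```

```
                     A
alpha_helix      83.33
three_ten_helix   0.00
beta_sheet       0.00
other            16.67
```

Ten of twelve residues are assigned H (83.33%); the two chain ends
cannot complete the i→i+4 hydrogen-bond pattern, which is exactly the
boundary behaviour a DSSP-style assigner should show.

Run one adsorption study on the conforming circular slot and compare
conditions:

```python
from graphsorb.pipeline import RunConfig, run_study, compare_replicates

report = run_study(RunConfig(pattern="CS2", seeds=(0, 1, 2)))
print(report.summary())
```

The toy system is a 48-bead cohesive homodimer (two 24-bead chains
linked by one bridge bond, chain A lower) placed exactly 12 Å above a
~12,800-atom patterned graphite slab.  Each seed is minimized, steered
onto the surface and relaxed; the report carries per-seed energy/RMSD/
Rg time series, contact tables and the final adsorption energies.  At
the packaged study conditions the post-relaxation mean adsorption-energy
magnitudes over five paired seeds are

```
flat  123.8 kJ/mol
SQ    137.0 kJ/mol   (square slot)
CS2   163.9 kJ/mol   (conforming circular slot)
```

i.e. the conforming slot binds the dimer ≈30% more strongly than the
flat surface while the generic square slot sits in between — the
qualitative ranking the pipeline is built to probe.  `compare_replicates`
turns per-condition energy vectors into pairwise paired t-tests (raw
and Holm-adjusted p-values).

A thin CLI wraps the same functions:

```bash
graphsorb build-substrate --pattern CS2 --out cs2.pdb
graphsorb make-fixture --kind ideal_helix --n 12 --out helix.pdb
graphsorb run --pattern CS2 --seeds 0,1,2 --outdir results/cs2
graphsorb compare flat=results/flat/manifest.json cs2=results/cs2/manifest.json
```

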