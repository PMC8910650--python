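"""Synthetic fixtures: ideal secondary-structure geometries, bead-spring
proteins and miniature substrates.

These generators stand in for downloaded crystal structures and the
full solvated system so that every stage of the pipeline is testable
offline.  Backbone geometries are built from internal coordinates
(standard bond lengths/angles, exact target dihedrals) with the NeRF
chain-extension construction; bead proteins are self-avoiding random
walks with analytically known reference metrics.  All generators are
pure functions of their arguments and seed.
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc

from graphsorb.lattice import AtomLattice, LatticeSpec, PatternSpec, build_flat, carve_pattern
from graphsorb.protein import ProteinModel

__all__ = [
    "make_ideal_helix",
    "make_extended_chain",
    "make_beta_hairpin",
    "make_bead_protein",
    "make_mini_substrate",
    "make_toy_dimer_system",
    "TOY_PRESETS",
]

# Standard backbone geometry (Å, degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_OMEGA = 180.0


def _extend(a: np.ndarray, b: np.ndarray, c: np.ndarray,
            bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d given a-b-c with |cd| = bond, angle(b,c,d) and
    torsion(a,b,c,d) in degrees (NeRF construction)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phi_psi: list[tuple[float, float]], chain: str = "A",
                    res_name: str = "ALA", res_start: int = 1) -> ProteinModel:
    """Poly-Ala backbone (N, CA, C, O per residue) with the given
    per-residue (phi, psi) targets; omega fixed trans."""
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")

    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = np.radians(_A_N_CA_C)
    C0 = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    C = [C0]

    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        n_i = _extend(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi_prev)
        ca_i = _extend(CA[i - 1], C[i - 1], n_i, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_i = _extend(C[i - 1], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi_psi[i][0])
        N.append(n_i)
        CA.append(ca_i)
        C.append(c_i)

    # Carbonyl oxygens: in the peptide plane, opposite the bisector of
    # the CA and next-N directions; the last residue uses a virtual N.
    O = []
    for i in range(n_res):
        if i + 1 < n_res:
            n_next = N[i + 1]
        else:
            n_next = _extend(N[i], CA[i], C[i], _B_C_N, _A_CA_C_N, phi_psi[i][1])
        u = (CA[i] - C[i]) / np.linalg.norm(CA[i] - C[i])
        w = (n_next - C[i]) / np.linalg.norm(n_next - C[i])
        d = -(u + w)
        O.append(C[i] + _B_C_O * d / np.linalg.norm(d))

    n_atoms = 4 * n_res
    arr = struc.AtomArray(n_atoms)
    coords, names, elements, res_ids = [], [], [], []
    for i in range(n_res):
        for name, pos, el in (("N", N[i], "N"), ("CA", CA[i], "C"),
                              ("C", C[i], "C"), ("O", O[i], "O")):
            coords.append(pos)
            names.append(name)
            elements.append(el)
            res_ids.append(res_start + i)
    arr.coord = np.array(coords, dtype=np.float32)
    arr.atom_name = np.array(names, dtype="U6")
    arr.element = np.array(elements, dtype="U2")
    arr.res_id = np.array(res_ids)
    arr.res_name = np.array([res_name] * n_atoms, dtype="U5")
    arr.chain_id = np.array([chain] * n_atoms, dtype="U4")
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    return ProteinModel(atoms=arr, metadata={"generator": "backbone", "n_res": n_res})


def make_ideal_helix(n: int, phi: float = -57.0, psi: float = -47.0) -> ProteinModel:
    """Ideal poly-Ala alpha-helix with exact (phi, psi) targets.

    Interior residues form the i -> i+4 O...N hydrogen-bond ladder by
    construction; the rise is ~1.5 Å per residue along the helix axis.
    """
    if n < 4:
        raise ValueError("a helix needs at least 4 residues")
    model = _build_backbone([(phi, psi)] * n)
    model.metadata["generator"] = "ideal_helix"
    return model


def make_extended_chain(n: int) -> ProteinModel:
    """Fully extended poly-Ala chain (phi = psi = 180): no H-bond pattern."""
    if n < 2:
        raise ValueError("need at least 2 residues")
    model = _build_backbone([(180.0, 180.0)] * n)
    model.metadata["generator"] = "extended_chain"
    return model


def make_beta_hairpin(n_per_strand: int = 6) -> ProteinModel:
    """Antiparallel beta-hairpin: two ideal strands joined by a tight turn.

    Strand residues use (phi, psi) = (-139, 135); the two-residue turn
    uses type-II' angles so the second strand runs back antiparallel and
    the cross-strand N-H...O=C ladder forms.
    """
    if n_per_strand < 3:
        raise ValueError("need at least 3 residues per strand")
    strand = (-139.0, 135.0)
    turn = [(60.0, -120.0), (-80.0, 0.0)]
    phi_psi = [strand] * n_per_strand + turn + [strand] * n_per_strand
    model = _build_backbone(phi_psi)
    model.metadata["generator"] = "beta_hairpin"
    return model


def _bead_model(coords: np.ndarray, chain: str, res_start: int = 1,
                mass: float = 110.0) -> struc.AtomArray:
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = np.array(["CA"] * n, dtype="U6")
    arr.element = np.array(["C"] * n, dtype="U2")
    arr.res_id = np.arange(res_start, res_start + n)
    arr.res_name = np.array(["ALA"] * n, dtype="U5")
    arr.chain_id = np.array([chain] * n, dtype="U4")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("mass", np.full(n, mass))
    arr.set_annotation("charge", np.zeros(n))
    return arr


def _saw_coords(n: int, b0: float, rng: np.random.Generator,
                min_sep: float, z_span: float, max_retry: int = 2000) -> np.ndarray:
    """Self-avoiding random walk with bond length b0, flattened into a
    slab of half-height z_span (side-on footprint)."""
    coords = [np.zeros(3)]
    for _ in range(1, n):
        for attempt in range(max_retry):
            d = rng.normal(size=3)
            d[2] *= 0.25  # bias steps toward the xy plane
            d = b0 * d / np.linalg.norm(d)
            cand = coords[-1] + d
            if abs(cand[2]) > z_span:  # keep the walk slab-shaped (side-on footprint)
                continue
            if len(coords) < 2 or np.min(
                np.linalg.norm(np.array(coords[:-1]) - cand, axis=1)) >= min_sep:
                coords.append(cand)
                break
        else:
            raise RuntimeError(
                f"self-avoiding walk failed after {max_retry} retries (n={n})"
            )
    return np.array(coords)


def make_bead_protein(n: int, b0: float = 3.8, seed: int = 0,
                      min_sep: float = 3.0) -> tuple[ProteinModel, dict]:
    """Self-avoiding bead-spring C-alpha chain plus analytic reference values.

    Returns (model, refs) where refs holds the exactly computed radius
    of gyration and the full pairwise distance table for cross-checking
    the conformation metrics.
    """
    if n < 2:
        raise ValueError("need at least 2 beads")
    rng = np.random.default_rng(seed)
    coords = _saw_coords(n, b0, rng, min_sep, z_span=b0)
    model = ProteinModel(atoms=_bead_model(coords, chain="A"),
                         metadata={"generator": "bead_protein", "seed": seed, "b0": b0})

    # references computed from the stored (PDB-precision) coordinates so
    # they agree exactly with any metric evaluated on the model
    stored = model.coords
    masses = np.full(n, 110.0)
    com = stored.mean(axis=0)  # equal masses
    rg = np.sqrt(np.sum(masses * np.sum((stored - com) ** 2, axis=1)) / masses.sum())
    diff = stored[:, None, :] - stored[None, :, :]
    refs = {"rg": float(rg), "distances": np.sqrt(np.sum(diff * diff, axis=2))}
    return model, refs


#: Miniature pattern presets scaled to the toy-dimer footprint.  CS2 is
#: a conforming spherical pocket: radius = globule radius + contact
#: distance, sunk so the wall wraps the dimer's lower half.  CS1's
#: small pit has a mouth narrower than the dimer, so it cannot conform;
#: SQ is a generic square slot with room to spare.
TOY_PRESETS: dict[str, PatternSpec] = {
    "flat": PatternSpec(kind="flat"),
    "LN1": PatternSpec(kind="linear_grating", width=30.0, depth=10.0),
    "LN2": PatternSpec(kind="linear_grating", width=15.0, depth=10.0, pitch=30.0),
    "CS1": PatternSpec(kind="circular_slot", radius=8.0, depth=0.0, hemisphere=True),
    "CS2": PatternSpec(kind="circular_slot", radius=11.5, depth=4.0, hemisphere=True),
    "SQ": PatternSpec(kind="square_slot", width=26.0, depth=10.0),
}


def make_mini_substrate(extent=(60.0, 60.0, 32.0), pattern: str | PatternSpec = "flat") -> AtomLattice:
    """Small graphite slab with an optional toy-scale pattern."""
    lattice = build_flat(LatticeSpec(target_extent=tuple(extent)))
    if isinstance(pattern, str):
        pattern = TOY_PRESETS[pattern]
    return carve_pattern(lattice, pattern)


def make_toy_dimer_system(pattern: str | PatternSpec = "flat", n_per_chain: int = 24,
                          seed: int = 0, gap: float = 12.0,
                          extent=(60.0, 60.0, 32.0), b0: float = 3.8):
    """Two linked bead chains above a miniature patterned substrate.

    Emulates the homodimer setup: chain A is the lower monomer close to
    the surface, chain B sits above it, and a single inter-chain bond at
    the middle beads stands in for the Cys78-Cys78 disulfide bridge.
    The minimum protein-substrate clearance is exactly ``gap`` Å.

    Non-bonded beads attract each other (native-contact cohesion), so
    under thermal motion the dimer compacts into a globule that keeps
    its shape like a folded protein instead of melting into a pancake;
    this is what lets a conforming slot out-adsorb a flat surface.
    """
    from graphsorb.energetics import ForceFieldParams
    from graphsorb.simulate import InternalModel
    from graphsorb.system import BoxConditions, SimulationSystem

    rng = np.random.default_rng(seed)
    lattice = make_mini_substrate(extent, pattern)

    a = _saw_coords(n_per_chain, b0, rng, min_sep=3.0, z_span=2.0)
    b = _saw_coords(n_per_chain, b0, rng, min_sep=3.0, z_span=2.0)
    b = b - b.mean(axis=0) + a.mean(axis=0) + np.array([0.0, 0.0, 6.0])

    coords = np.vstack([a, b])
    center = lattice.footprint_center
    coords[:, 0] += center[0] - coords[:, 0].mean()
    coords[:, 1] += center[1] - coords[:, 1].mean()
    coords[:, 2] += (lattice.z_top + gap) - coords[:, 2].min()

    arr_a = _bead_model(coords[:n_per_chain], chain="A")
    arr_b = _bead_model(coords[n_per_chain:], chain="B", res_start=1)
    arr = arr_a + arr_b
    model = ProteinModel(atoms=arr, metadata={"generator": "toy_dimer", "seed": seed})

    n = 2 * n_per_chain
    bonds = [[i, i + 1] for i in range(n_per_chain - 1)]
    bonds += [[n_per_chain + i, n_per_chain + i + 1] for i in range(n_per_chain - 1)]
    mid = n_per_chain // 2
    link = [mid, n_per_chain + mid]
    link_len = float(np.linalg.norm(coords[link[0]] - coords[link[1]]))
    bonds.append(link)
    bonds = np.array(bonds, dtype=int)
    b0s = np.full(len(bonds), b0)
    b0s[-1] = link_len
    internal = InternalModel(
        bonds=bonds,
        bond_b0=b0s,
        bond_k=np.full(len(bonds), 400.0),
        nb_sigma=4.0,
        nb_epsilon=3.0,  # cohesive: ~1.2 kT at 310 K keeps a folded, compact globule
        wca=False,
        n_atoms=n,
    )

    box = BoxConditions(lx=lattice.cell[0], ly=lattice.cell[1],
                        z_lo=0.0, z_hi=coords[:, 2].max() + 40.0)
    return SimulationSystem(
        protein=model,
        lattice=lattice,
        box=box,
        ff=ForceFieldParams(),
        internal=internal,
        metadata={"pattern": pattern if isinstance(pattern, str) else pattern.kind,
                  "seed": seed, "gap": gap},
    )
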