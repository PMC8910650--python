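"""Protein structures: PDB input, protonation tagging, receptor-binding
epitopes, and rigid-body placement above a substrate.

The atom container is a :class:`biotite.structure.AtomArray` wrapped in
:class:`ProteinModel`, which adds per-atom masses, formal charges and a
histidine tautomer tag, plus backbone bookkeeping used by the
conformational analyses.

Protonation follows the physiological convention used throughout the
study: Lys/Arg protonated (+1), Glu/Asp deprotonated (-1), and every
histidine treated as the neutral N-epsilon tautomer HSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

__all__ = [
    "ProteinModel",
    "EpitopeSelection",
    "read_pdb",
    "assign_protonation",
    "select_epitopes",
    "place_above_substrate",
]

_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845,
}

#: Formal charges assigned per residue under the physiological protonation scheme
FORMAL_CHARGES = {"LYS": 1, "ARG": 1, "GLU": -1, "ASP": -1}

#: Residue names recognised as standard amino acids (charge 0 unless listed above)
_STANDARD = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSE",
    "HSD", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}


def _element_mass(el: str) -> float:
    return _ELEMENT_MASS.get(el.upper(), 12.011)


@dataclass
class ProteinModel:
    """A protein as atoms + residue/backbone bookkeeping.

    ``atoms`` is a biotite ``AtomArray`` carrying at least atom_name,
    element, res_id, res_name and chain_id annotations; this class adds
    ``mass`` (amu) and ``charge`` (partial charge, e) annotations if
    missing.  Chain ids double as monomer labels (A = lower monomer in
    an adsorption setup).
    """

    atoms: struc.AtomArray
    tautomers: dict = field(default_factory=dict)   # (chain, res_id) -> tag e.g. "HSE"
    formal_charges: dict = field(default_factory=dict)  # (chain, res_id) -> int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.atoms
        if "mass" not in arr.get_annotation_categories():
            arr.set_annotation("mass", np.array([_element_mass(e) for e in arr.element]))
        if "charge" not in arr.get_annotation_categories():
            arr.set_annotation("charge", np.zeros(arr.array_length()))
        if np.any(arr.mass <= 0):
            raise ValueError("all atomic masses must be positive")

    # ------------------------------------------------------------------ basics
    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.atoms.coord, dtype=float)

    @coords.setter
    def coords(self, value: np.ndarray) -> None:
        self.atoms.coord = np.asarray(value, dtype=np.float32).reshape(-1, 3)

    @property
    def masses(self) -> np.ndarray:
        return np.asarray(self.atoms.mass, dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.asarray(self.atoms.charge, dtype=float)

    @property
    def chains(self) -> list[str]:
        return sorted(set(self.atoms.chain_id))

    def write_pdb(self, path) -> None:
        """Write the current coordinates as a single-model PDB file."""
        import biotite.structure.io.pdb as pdb

        f = pdb.PDBFile()
        pdb.set_structure(f, self.atoms)
        f.write(str(path))

    def copy(self) -> "ProteinModel":
        return ProteinModel(
            atoms=self.atoms.copy(),
            tautomers=dict(self.tautomers),
            formal_charges=dict(self.formal_charges),
            metadata=dict(self.metadata),
        )

    # ------------------------------------------------------------- residues
    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, res_id, res_name) triples."""
        seen, out = set(), []
        arr = self.atoms
        for c, i, n in zip(arr.chain_id, arr.res_id, arr.res_name):
            key = (c, int(i))
            if key not in seen:
                seen.add(key)
                out.append((c, int(i), n))
        return out

    def backbone_indices(self) -> dict[tuple[str, int], dict[str, int]]:
        """Per-residue indices of backbone N, CA, C (missing atoms absent)."""
        arr = self.atoms
        out: dict[tuple[str, int], dict[str, int]] = {}
        for idx, (c, i, name) in enumerate(zip(arr.chain_id, arr.res_id, arr.atom_name)):
            if name in ("N", "CA", "C", "O"):
                out.setdefault((c, int(i)), {})[name] = idx
        return out

    def incomplete_residues(self) -> list[tuple[str, int]]:
        """Residues missing any of the backbone heavy atoms N, CA, C."""
        bb = self.backbone_indices()
        bad = []
        for c, i, _ in self.residues():
            have = bb.get((c, int(i)), {})
            if not {"N", "CA", "C"} <= set(have):
                bad.append((c, int(i)))
        return bad

    def net_formal_charge(self, termini: bool = False) -> int:
        """Net protein formal charge under the assigned protonation tags.

        With ``termini=True`` each chain contributes +1 (N-terminus) and
        -1 (C-terminus), which cancel; default is neutral caps.
        """
        q = sum(self.formal_charges.values())
        if termini:
            q += sum(+1 - 1 for _ in self.chains)
        return int(q)


@dataclass(frozen=True)
class EpitopeSelection:
    """Receptor-binding residue sets per monomer.

    wrist residues (ids 49-63) contact the type I receptor; knuckle
    residues (34, 39, 88, 90, 100) contact the type II receptor.
    """

    wrist: dict  # chain -> tuple of residue ids
    knuckle: dict


WRIST_RANGE = tuple(range(49, 64))
KNUCKLE_IDS = (34, 39, 88, 90, 100)
_EXPECTED_NAMES = {49: "PHE", 63: "VAL", 34: "ALA", 39: "HIS", 88: "SER", 90: "LEU", 100: "LEU"}


def read_pdb(path) -> ProteinModel:
    """Read a PDB file into a :class:`ProteinModel`.

    Atoms are grouped by chain with the file's residue numbering
    preserved.  Altloc duplicates keep the highest-occupancy copy.
    Residues missing backbone heavy atoms are recorded in
    ``metadata["incomplete_residues"]``, not dropped.
    """
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    arr = f.get_structure(model=1, altloc="occupancy")
    arr = arr[~struc.filter_solvent(arr)]
    arr = arr[arr.element != ""]
    if arr.array_length() == 0:
        raise ValueError(f"{path}: no atom records found")
    model = ProteinModel(atoms=arr)
    missing = model.incomplete_residues()
    if missing:
        warnings.warn(f"{len(missing)} residues missing backbone heavy atoms: {missing[:5]}...")
    model.metadata["incomplete_residues"] = missing
    model.metadata["source"] = str(path)
    return model


def assign_protonation(model: ProteinModel, termini: bool = False) -> ProteinModel:
    """Tag formal charges and histidine tautomers; coordinates untouched.

    Lys/Arg -> +1, Glu/Asp -> -1, His -> HSE tag (neutral), all other
    residues 0.  Unknown residue names get charge 0 with a warning.
    """
    out = model.copy()
    for chain, res_id, res_name in out.residues():
        name = res_name.upper()
        if name not in _STANDARD:
            warnings.warn(f"unknown residue {res_name} {chain}{res_id}; assuming neutral")
        out.formal_charges[(chain, res_id)] = FORMAL_CHARGES.get(name, 0)
        if name in ("HIS", "HSD", "HSP", "HSE"):
            out.tautomers[(chain, res_id)] = "HSE"
            out.formal_charges[(chain, res_id)] = 0
    out.metadata["termini_charged"] = termini
    return out


def select_epitopes(model: ProteinModel) -> EpitopeSelection:
    """Select wrist (49-63) and knuckle (34/39/88/90/100) residues per monomer."""
    present: dict[str, dict[int, str]] = {}
    for chain, res_id, res_name in model.residues():
        present.setdefault(chain, {})[res_id] = res_name.upper()

    wrist, knuckle = {}, {}
    for chain, res_map in present.items():
        missing = [i for i in (*WRIST_RANGE, *KNUCKLE_IDS) if i not in res_map]
        if missing:
            raise ValueError(f"chain {chain}: missing epitope residues {sorted(set(missing))}")
        for i, expected in _EXPECTED_NAMES.items():
            if res_map[i] not in (expected,):
                warnings.warn(
                    f"chain {chain} residue {i}: expected {expected}, found {res_map[i]}"
                )
        wrist[chain] = WRIST_RANGE
        knuckle[chain] = KNUCKLE_IDS
    return EpitopeSelection(wrist=wrist, knuckle=knuckle)


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Rows are principal axes sorted by decreasing extent (right-handed)."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    axes = evecs[:, ::-1].T  # largest first
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def place_above_substrate(model: ProteinModel, lattice, gap: float = 12.0,
                          orientation: str = "side_on", ff=None, center=None):
    """Rigid-body place the protein above the substrate in side-on orientation.

    Side-on means the protein's longest principal axis lies in the x-y
    plane.  The protein is centred over ``center`` (default: the carved
    pattern centre, else the cell centre) with a vertical clearance of
    exactly ``gap`` between its lowest atom and the top substrate atom.
    """
    if orientation != "side_on":
        raise ValueError(f"unsupported orientation {orientation!r}")
    from graphsorb.system import SimulationSystem, BoxConditions
    from graphsorb.energetics import ForceFieldParams

    out = model.copy()
    coords = out.coords
    axes = _principal_axes(coords)
    com = coords.mean(axis=0)
    rotated = (coords - com) @ axes.T  # largest axis -> x, smallest -> z

    pattern = lattice.meta.get("pattern")
    if center is None:
        if pattern is not None and getattr(pattern, "center", None) is not None:
            center = pattern.center
        else:
            center = lattice.footprint_center

    extent = np.ptp(rotated, axis=0)
    if lattice.cell[0] > 0 and (extent[0] > lattice.cell[0] or extent[1] > lattice.cell[1]):
        raise ValueError(
            f"protein footprint {extent[:2]} Å exceeds periodic cell {lattice.cell} Å"
        )

    rotated[:, 0] += center[0] - rotated[:, 0].mean()
    rotated[:, 1] += center[1] - rotated[:, 1].mean()
    rotated[:, 2] += (lattice.z_top + gap) - rotated[:, 2].min()
    out.coords = rotated

    z_hi = rotated[:, 2].max() + 30.0
    box = BoxConditions(lx=lattice.cell[0], ly=lattice.cell[1], z_lo=0.0, z_hi=z_hi)
    return SimulationSystem(
        protein=out,
        lattice=lattice,
        box=box,
        ff=ff if ff is not None else ForceFieldParams(),
    )
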