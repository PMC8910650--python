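"""Trajectory conformation metrics.

* RMSD against the first frame, computed in the substrate-fixed lab
  frame (no superposition by default: a Kabsch fit would mask
  adsorption-driven rigid motion toward the surface).
* Mass-weighted radius of gyration.
* Backbone phi/psi dihedrals with Ramachandran classification against a
  replaceable region map (favored / allowed / disallowed).
* DSSP-style secondary-structure assignment from a backbone hydrogen-bond
  energy criterion, with amide hydrogens reconstructed geometrically
  (crystal structures carry no H).  Helix classes H (alpha, i->i+4 turn
  runs) and G (3-10, i->i+3), strand E from Kabsch-Sander bridge rules;
  everything else is lumped as other/coil.  Content tables report the
  percentage of residues per class and monomer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "rmsd",
    "radius_of_gyration",
    "dihedral",
    "backbone_dihedrals",
    "load_region_map",
    "ramachandran_classify",
    "assign_secondary_structure",
    "ss_content_table",
]


# --------------------------------------------------------------------------- trajectory
@dataclass
class Trajectory:
    """Ordered protein coordinate frames with timestamps (ps).

    The first frame is the reference for deviation metrics.
    """

    frames: np.ndarray  # (T, N, 3) Å
    times: np.ndarray   # (T,) ps
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, N, 3)")
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def write_xyz(self, path, elements=None) -> None:
        elements = elements if elements is not None else ["C"] * self.n_atoms
        with open(path, "w") as fh:
            for t, frame in zip(self.times, self.frames):
                fh.write(f"{self.n_atoms}\nt = {t:.4f} ps\n")
                for el, (x, y, z) in zip(elements, frame):
                    fh.write(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")

    def write_pdb(self, path, model) -> None:
        """Write as a multi-model PDB using the model's atom annotations."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        template = model.atoms
        stack = struc.stack([template] * self.n_frames)
        stack.coord = self.frames.astype(np.float32)
        f = pdb.PDBFile()
        pdb.set_structure(f, stack)
        f.write(str(path))


def rmsd(traj: Trajectory, mode: str = "per_frame", atom_indices=None,
         superpose: bool = False):
    """Root-mean-square deviation from the first frame.

    ``per_frame`` returns the RMSD time series; ``time_averaged``
    returns the mean of the per-frame values.  No superposition is
    applied unless ``superpose=True`` (optional Kabsch fit).
    """
    frames = traj.frames
    if atom_indices is not None:
        frames = frames[:, atom_indices]
    ref = frames[0]
    out = np.empty(len(frames))
    for j, frame in enumerate(frames):
        moved = frame
        if superpose and j > 0:
            from scipy.spatial.transform import Rotation

            a = frame - frame.mean(axis=0)
            b = ref - ref.mean(axis=0)
            rot, _ = Rotation.align_vectors(b, a)
            moved = rot.apply(a) + ref.mean(axis=0)
        out[j] = np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))
    if mode == "per_frame":
        return out
    if mode == "time_averaged":
        return float(out.mean())
    raise ValueError(f"unknown mode {mode!r}")


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration about the centre of mass, Å."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (coords * masses[:, None]).sum(axis=0) / total
    return float(np.sqrt(np.sum(masses * np.sum((coords - com) ** 2, axis=1)) / total))


def rg_series(traj: Trajectory, masses: np.ndarray) -> np.ndarray:
    return np.array([radius_of_gyration(f, masses) for f in traj.frames])


# --------------------------------------------------------------------------- dihedrals
def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    ang = -np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


_PEPTIDE_BOND_MAX = 2.0  # Å, C(i-1)-N(i) distance marking chain continuity


def backbone_dihedrals(model, coords: np.ndarray | None = None) -> pd.DataFrame:
    """Per-residue (phi, psi) in degrees; NaN where undefined (termini,
    chain breaks, missing backbone atoms)."""
    bb = model.backbone_indices()
    xyz = model.coords if coords is None else np.asarray(coords, dtype=float)
    residues = model.residues()
    rows = []
    by_chain: dict[str, list[tuple[int, str]]] = {}
    for chain, res_id, res_name in residues:
        by_chain.setdefault(chain, []).append((res_id, res_name))

    for chain, res_list in by_chain.items():
        for k, (res_id, res_name) in enumerate(res_list):
            cur = bb.get((chain, res_id), {})
            phi = psi = np.nan
            if {"N", "CA", "C"} <= set(cur):
                n, ca, c = xyz[cur["N"]], xyz[cur["CA"]], xyz[cur["C"]]
                if k > 0:
                    prev = bb.get((chain, res_list[k - 1][0]), {})
                    if "C" in prev and np.linalg.norm(n - xyz[prev["C"]]) < _PEPTIDE_BOND_MAX:
                        phi = dihedral(xyz[prev["C"]], n, ca, c)
                if k + 1 < len(res_list):
                    nxt = bb.get((chain, res_list[k + 1][0]), {})
                    if "N" in nxt and np.linalg.norm(xyz[nxt["N"]] - c) < _PEPTIDE_BOND_MAX:
                        psi = dihedral(n, ca, c, xyz[nxt["N"]])
            rows.append({"monomer": chain, "res_id": res_id, "res_name": res_name,
                         "phi": phi, "psi": psi})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- Ramachandran regions
def load_region_map(path=None) -> dict:
    """Load the Ramachandran region polygons (favored/allowed) from JSON."""
    if path is None:
        with resources.files("graphsorb.data").joinpath("rama_regions.json").open() as fh:
            raw = json.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    return {
        tier: {name: np.asarray(poly, dtype=float) for name, poly in raw[tier].items()}
        for tier in ("favored", "allowed")
    }


def _in_any_polygon(points: np.ndarray, polygons) -> np.ndarray:
    from matplotlib.path import Path

    inside = np.zeros(len(points), dtype=bool)
    for poly in polygons:
        inside |= Path(poly).contains_points(points)
    return inside


def ramachandran_classify(phi, psi, region_map: dict | None = None) -> np.ndarray:
    """Classify (phi, psi) pairs as favored / allowed / disallowed.

    A pure function of the angles and the region map; NaN angles give
    the label ``undefined``.
    """
    if region_map is None:
        region_map = load_region_map()
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    pts = np.column_stack([phi, psi])
    labels = np.full(len(pts), "disallowed", dtype=object)
    ok = ~(np.isnan(phi) | np.isnan(psi))
    allowed = _in_any_polygon(pts[ok], region_map["allowed"].values())
    favored = _in_any_polygon(pts[ok], region_map["favored"].values())
    sub = np.full(ok.sum(), "disallowed", dtype=object)
    sub[allowed] = "allowed"
    sub[favored] = "favored"
    labels[ok] = sub
    labels[~ok] = "undefined"
    return labels


def ramachandran_records(model, coords=None, region_map=None) -> pd.DataFrame:
    """Dihedral table with Ramachandran region labels per residue."""
    df = backbone_dihedrals(model, coords)
    df["region"] = ramachandran_classify(df["phi"].to_numpy(), df["psi"].to_numpy(), region_map)
    return df


# ------------------------------------------------------------- secondary structure
_HB_Q1Q2_F = 27.888  # kcal Å/mol, Kabsch-Sander electrostatic H-bond factor
_HB_CUTOFF = -0.5    # kcal/mol
_NH_LENGTH = 1.01    # Å


def _chain_backbone(model, xyz):
    """Per chain: ordered residue keys and their N/CA/C/O coordinates."""
    bb = model.backbone_indices()
    chains: dict[str, list] = {}
    for chain, res_id, res_name in model.residues():
        atoms = bb.get((chain, res_id), {})
        if {"N", "CA", "C", "O"} <= set(atoms):
            entry = {k: xyz[v] for k, v in atoms.items()}
        else:
            entry = None
        chains.setdefault(chain, []).append(((chain, res_id), res_name, entry))
    return chains


def _hbond_energy(donor, acceptor) -> float:
    """Kabsch-Sander electrostatic energy (kcal/mol) of N-H(donor)...O=C(acceptor)."""
    n, h = donor["N"], donor["H"]
    c, o = acceptor["C"], acceptor["O"]
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return 0.0
    return _HB_Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(model, coords: np.ndarray | None = None) -> pd.DataFrame:
    """DSSP-style per-residue secondary structure.

    Returns a frame with columns monomer, res_id, res_name, ss where ss
    is H (alpha helix), G (3-10 helix), E (beta strand/bridge) or C
    (other).  Residues with incomplete backbones are C.  Chains shorter
    than 5 residues cannot host a helix.
    """
    xyz = model.coords if coords is None else np.asarray(coords, dtype=float)
    chains = _chain_backbone(model, xyz)

    # Flatten to a global residue list; record chain boundaries.
    entries = []      # dicts with N/CA/C/O/H or None
    keys, names, chain_of = [], [], []
    for chain, rows in chains.items():
        prev = None
        for key, res_name, entry in rows:
            if entry is not None:
                # Reconstruct the amide H along the C(i-1)=O(i-1) direction
                # (first residue of a chain has no donor H).
                connected = (
                    prev is not None
                    and np.linalg.norm(entry["N"] - prev["C"]) < _PEPTIDE_BOND_MAX
                )
                if connected:
                    direction = prev["C"] - prev["O"]
                    direction = direction / np.linalg.norm(direction)
                    entry = dict(entry, H=entry["N"] + _NH_LENGTH * direction)
                else:
                    entry = dict(entry)
            entries.append(entry)
            keys.append(key)
            names.append(res_name)
            chain_of.append(chain)
            prev = entry
    n = len(entries)

    # Hydrogen bonds: hb[a][d] True if N-H of residue d donates to C=O of a.
    ca_coords = np.array([
        e["CA"] if e is not None else [1e6, 1e6, 1e6] for e in entries
    ])
    from scipy.spatial import cKDTree

    tree = cKDTree(ca_coords)
    candidate_pairs = tree.query_pairs(9.0, output_type="ndarray")
    if len(candidate_pairs):
        candidate_pairs = np.vstack([candidate_pairs, candidate_pairs[:, ::-1]])
    hb = [set() for _ in range(n)]  # hb[acceptor] = {donors}
    for a, d in candidate_pairs:
        a, d = int(a), int(d)
        ea, ed = entries[a], entries[d]
        if ea is None or ed is None or "H" not in ed:
            continue
        if chain_of[a] == chain_of[d] and abs(a - d) < 2:
            continue
        if _hbond_energy(ed, ea) < _HB_CUTOFF:
            hb[a].add(d)

    def turn(i: int, k: int) -> bool:
        j = i + k
        return (
            j < n and chain_of[i] == chain_of[j] and (i + k) in hb[i]
        )

    ss = np.array(["C"] * n, dtype=object)

    # 3-10 helices: two consecutive 3-turns -> G for residues i..i+2
    for i in range(1, n - 3):
        if turn(i - 1, 3) and turn(i, 3):
            ss[i:i + 3] = "G"

    # beta bridges (Kabsch-Sander rules): residues i, j with |i-j| >= 3
    # (or on different chains) bridged through the N-H...O=C ladder.
    def hbond(a: int, d: int) -> bool:
        return 0 <= a < n and 0 <= d < n and d in hb[a]

    bridge_candidates = tree.query_pairs(6.5, output_type="ndarray")
    for i, j in bridge_candidates:
        i, j = int(min(i, j)), int(max(i, j))
        if chain_of[i] == chain_of[j] and j - i < 3:
            continue
        parallel = (hbond(i - 1, j) and hbond(j, i + 1)) or (hbond(j - 1, i) and hbond(i, j + 1))
        anti = (hbond(i, j) and hbond(j, i)) or (hbond(i - 1, j + 1) and hbond(j - 1, i + 1))
        if parallel or anti:
            ss[i] = "E"
            ss[j] = "E"

    # alpha helices: two consecutive 4-turns -> H for residues i..i+3 (priority over E/G)
    for i in range(1, n - 4):
        if turn(i - 1, 4) and turn(i, 4):
            ss[i:i + 4] = "H"

    return pd.DataFrame({
        "monomer": chain_of,
        "res_id": [k[1] for k in keys],
        "res_name": names,
        "ss": ss,
    })


def ss_content_table(ss_df: pd.DataFrame) -> pd.DataFrame:
    """Secondary-structure content (%) per monomer, rounded to 2 decimals.

    Rows: alpha_helix (H), three_ten_helix (G), beta_sheet (E), other.
    Percentages per monomer sum to exactly 100 before rounding.
    """
    rows = {"alpha_helix": "H", "three_ten_helix": "G", "beta_sheet": "E"}
    out = {}
    for monomer, grp in ss_df.groupby("monomer"):
        total = len(grp)
        col = {}
        for label, code in rows.items():
            col[label] = round(100.0 * (grp["ss"] == code).sum() / total, 2)
        col["other"] = round(100.0 * (~grp["ss"].isin(list(rows.values()))).sum() / total, 2)
        out[monomer] = col
    return pd.DataFrame(out)
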