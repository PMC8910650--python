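"""Atomistic graphite (001) slabs and nanoscale surface topographies.

Graphite is modelled as stacked honeycomb carbon layers on an
orthorhombic cell.  With C-C bond length ``L`` the rectangular in-plane
repeat is ``(sqrt(3)*L, 3*L)`` containing four atoms; AB-stacked layers
are offset by one bond length along y.  With the default ``L = 1.418`` Å
this gives the conventional half-cell parameters a = 1.228 Å and
b = 2.127 Å (half of 2.456 / 4.254) and an interlayer spacing of
3.348 Å (c = 6.696 Å for the two-layer repeat).

Topographies are carved by deleting atoms strictly inside an exclusion
region cut into the top of a flat slab: linear gratings (rectangular
grooves, optionally repeated at a pitch), square slots, and circular
slots realised as hemicylindrical grooves or hemispherical pits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from graphsorb.constants import CC_BOND, INTERLAYER

__all__ = [
    "LatticeSpec",
    "PatternSpec",
    "AtomLattice",
    "build_flat",
    "carve_pattern",
    "write_structure",
    "PATTERN_PRESETS",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of a graphite (001) slab to be generated.

    Parameters
    ----------
    target_extent : (float, float, float)
        Requested slab size in Å.  The generated periodic cell is the
        largest integer multiple of the in-plane repeat not exceeding
        the x/y targets, so periodic images are commensurate; the layer
        count is ``floor(z / interlayer) + 1``.
    cc_bond : float
        C-C bond length in Å.
    interlayer : float
        Spacing between basal planes in Å.
    stacking : str
        ``"AB"`` (graphite) or ``"AA"``.
    """

    target_extent: tuple[float, float, float]
    cc_bond: float = CC_BOND
    interlayer: float = INTERLAYER
    stacking: str = "AB"
    plane: str = "(001)"

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.target_extent):
            raise ValueError("all extents must be positive")
        if self.cc_bond <= 0 or self.interlayer <= 0:
            raise ValueError("cc_bond and interlayer must be positive")
        if self.stacking not in ("AA", "AB"):
            raise ValueError(f"unknown stacking {self.stacking!r}")

    @property
    def repeat(self) -> tuple[float, float]:
        """In-plane orthorhombic repeat (x, y) in Å."""
        return (math.sqrt(3.0) * self.cc_bond, 3.0 * self.cc_bond)


@dataclass(frozen=True)
class PatternSpec:
    """A nanoscale exclusion carved into the top of a slab.

    kind is one of ``flat``, ``linear_grating``, ``square_slot``,
    ``circular_slot``.  ``width``/``depth`` size rectangular exclusions;
    ``pitch`` repeats grating grooves; ``center`` is the (x, y) pattern
    centre, defaulting to the slab centre.

    A circular slot excludes a circular cross-section (a cylinder along
    y, or a sphere with ``hemisphere=True``) of radius ``radius`` whose
    axis sits ``depth`` Å below the top surface: depth 0 gives an open
    hemicylindrical groove, while depth > 0 sinks the circle so the
    mouth narrows and the walls overhang, a slot profile that can
    conform around an adsorbate.
    """

    kind: str = "flat"
    width: float = 0.0
    depth: float = 0.0
    pitch: float | None = None
    radius: float = 0.0
    center: tuple[float, float] | None = None
    hemisphere: bool = False

    def __post_init__(self) -> None:
        kinds = ("flat", "linear_grating", "square_slot", "circular_slot")
        if self.kind not in kinds:
            raise ValueError(f"unknown pattern kind {self.kind!r}; expected one of {kinds}")
        if self.kind in ("linear_grating", "square_slot") and self.width < 0:
            raise ValueError("width must be non-negative")
        if self.kind == "circular_slot" and self.radius < 0:
            raise ValueError("radius must be non-negative")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass
class AtomLattice:
    """A rigid substrate: atom positions, element symbols and the periodic cell.

    Positions are in Å with the origin at the slab's lower-left-bottom
    corner; the cell is periodic in x and y only.  Substrate atoms are
    always treated as fixed.
    """

    positions: np.ndarray
    elements: list[str]
    cell: tuple[float, float]
    fixed: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.positions):
            raise ValueError("elements and positions length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def z_top(self) -> float:
        """Height of the highest substrate atom (0 for an empty lattice)."""
        return float(self.positions[:, 2].max()) if self.n_atoms else 0.0

    @property
    def footprint_center(self) -> tuple[float, float]:
        return (self.cell[0] / 2.0, self.cell[1] / 2.0)


# Four-atom basis of the rectangular honeycomb cell, in units of cc_bond.
_BASIS = np.array([
    [0.0, 0.0],
    [math.sqrt(3.0) / 2.0, 0.5],
    [math.sqrt(3.0) / 2.0, 1.5],
    [0.0, 2.0],
])


def build_flat(spec: LatticeSpec) -> AtomLattice:
    """Generate a flat graphite (001) slab filling ``spec.target_extent``.

    The returned cell is the nearest integer multiple of the
    orthorhombic repeat not exceeding the x/y targets, so the slab
    tiles periodically without seams.  Layers are stacked downward from
    the top surface; layer count is ``floor(z_extent/interlayer) + 1``.
    """
    rx, ry = spec.repeat
    ex, ey, ez = spec.target_extent
    nx, ny = int(ex // rx), int(ey // ry)
    n_layers = int(ez // spec.interlayer) + 1
    if nx < 1 or ny < 1:
        raise ValueError(
            f"target extent ({ex:g}, {ey:g}) Å smaller than one unit cell; "
            f"minimum buildable size is ({rx:.3f}, {ry:.3f}) Å"
        )

    basis = _BASIS * spec.cc_bond
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    origins = np.stack([ix.ravel() * rx, iy.ravel() * ry], axis=1)
    layer_xy = (origins[:, None, :] + basis[None, :, :]).reshape(-1, 2)

    cell = (nx * rx, ny * ry)
    shift_ab = np.array([0.0, spec.cc_bond])
    frames = []
    for k in range(n_layers):
        xy = layer_xy.copy()
        if spec.stacking == "AB" and k % 2 == 1:
            xy = (xy + shift_ab) % np.array(cell)
        z = np.full(len(xy), k * spec.interlayer)
        frames.append(np.column_stack([xy, z]))
    pos = np.concatenate(frames)
    return AtomLattice(
        positions=pos,
        elements=["C"] * len(pos),
        cell=cell,
        meta={"spec": spec, "n_layers": n_layers, "pattern": None},
    )


def _exclusion_mask(lattice: AtomLattice, pattern: PatternSpec) -> np.ndarray:
    """Boolean mask of atoms strictly inside the exclusion region."""
    pos = lattice.positions
    if pattern.kind == "flat" or lattice.n_atoms == 0:
        return np.zeros(lattice.n_atoms, dtype=bool)

    cx, cy = pattern.center if pattern.center is not None else lattice.footprint_center
    z_top = lattice.z_top
    x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
    above_floor = z > z_top - pattern.depth  # strictly inside: depth 0 removes nothing

    if pattern.kind == "linear_grating":
        half = pattern.width / 2.0
        if half <= 0:
            return np.zeros(lattice.n_atoms, dtype=bool)
        if pattern.pitch and pattern.pitch > 0:
            # grooves repeated at the pitch, phase-anchored at the centre
            dx = np.abs((x - cx + pattern.pitch / 2.0) % pattern.pitch - pattern.pitch / 2.0)
        else:
            dx = np.abs(x - cx)
        return (dx < half) & above_floor

    if pattern.kind == "square_slot":
        half = pattern.width / 2.0
        return (np.abs(x - cx) < half) & (np.abs(y - cy) < half) & above_floor

    # circular_slot: circular cross-section with its axis pattern.depth
    # below the top surface (cylinder along y, or sphere if hemisphere).
    r2 = pattern.radius**2
    z_axis = z_top - pattern.depth
    if pattern.hemisphere:
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - z_axis) ** 2
    else:
        d2 = (x - cx) ** 2 + (z - z_axis) ** 2
    return d2 < r2


def carve_pattern(lattice: AtomLattice, pattern: PatternSpec) -> AtomLattice:
    """Remove atoms strictly inside the pattern's exclusion region.

    The surviving atom set is a subset of the input set and the
    operation is idempotent.  A zero-size pattern is an exact no-op.
    """
    thickness = float(np.ptp(lattice.positions[:, 2])) if lattice.n_atoms else 0.0
    reach = pattern.depth + (pattern.radius if pattern.kind == "circular_slot" else 0.0)
    if reach > thickness and lattice.n_atoms and pattern.kind != "flat":
        raise ValueError(
            f"pattern depth {reach:g} Å exceeds slab thickness {thickness:g} Å"
        )
    mask = _exclusion_mask(lattice, pattern)
    keep = ~mask
    meta = dict(lattice.meta)
    meta["pattern"] = pattern
    meta["n_removed"] = int(mask.sum())
    return AtomLattice(
        positions=lattice.positions[keep],
        elements=[e for e, k in zip(lattice.elements, keep) if k],
        cell=lattice.cell,
        fixed=lattice.fixed,
        meta=meta,
    )


# Qualitative presets for the six study topographies.  Widths, depths and
# radii other than the 90 Å LN1 grating width are presets chosen to be
# geometrically sensible (e.g. the CS2 radius conforms to a ~50 Å protein
# footprint), not measured values.
PATTERN_PRESETS: dict[str, PatternSpec] = {
    "flat": PatternSpec(kind="flat"),
    "LN1": PatternSpec(kind="linear_grating", width=90.0, depth=13.392, pitch=180.0),
    "LN2": PatternSpec(kind="linear_grating", width=45.0, depth=13.392, pitch=90.0),
    "CS1": PatternSpec(kind="circular_slot", radius=15.0, depth=0.0, hemisphere=True),
    "CS2": PatternSpec(kind="circular_slot", radius=20.0, depth=5.0),
    "SQ": PatternSpec(kind="square_slot", width=50.0, depth=16.74),
}


def _as_atom_array(positions: np.ndarray, elements: list[str], cell: tuple[float, float] | None):
    import biotite.structure as struc

    n = len(positions)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(positions, dtype=np.float32).reshape(-1, 3)
    arr.element = np.array([e.upper() for e in elements], dtype="U2")
    arr.atom_name = np.array([e.upper() for e in elements], dtype="U6")
    arr.res_name = np.array(["SUB"] * n, dtype="U5")
    arr.res_id = (np.arange(n) % 9999) + 1  # stay within PDB res-id field width
    arr.chain_id = np.array(["S"] * n, dtype="U4")
    arr.hetero = np.array([True] * n)
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("b_factor", np.zeros(n))
    if cell is not None:
        zlen = float(np.ptp(positions[:, 2])) + 10.0 if n else 10.0
        arr.box = np.diag([cell[0], cell[1], zlen])
    return arr


def write_structure(obj, path, fmt: str | None = None) -> None:
    """Write an :class:`AtomLattice` (or anything with positions/elements)
    to PDB or XYZ.  ``fmt`` defaults to the file extension."""
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1]
    fmt = fmt.upper()

    positions = np.asarray(obj.positions, dtype=float).reshape(-1, 3)
    elements = list(obj.elements)
    cell = getattr(obj, "cell", None)

    if fmt == "PDB":
        import biotite.structure.io.pdb as pdb

        f = pdb.PDBFile()
        pdb.set_structure(f, _as_atom_array(positions, elements, cell))
        f.write(path)
    elif fmt == "XYZ":
        with open(path, "w") as fh:
            fh.write(f"{len(positions)}\n")
            fh.write("generated by graphsorb\n")
            for el, (x, y, z) in zip(elements, positions):
                fh.write(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}; use PDB or XYZ")


def read_structure(path, fmt: str | None = None) -> AtomLattice:
    """Read coordinates back from a PDB or XYZ file into an AtomLattice."""
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1]
    fmt = fmt.upper()
    if fmt == "PDB":
        import biotite.structure.io.pdb as pdb

        f = pdb.PDBFile.read(path)
        if f.get_model_count() == 0:
            return AtomLattice(np.empty((0, 3)), [], cell=(0.0, 0.0))
        arr = f.get_structure(model=1)
        cell = (0.0, 0.0)
        if arr.box is not None:
            cell = (float(arr.box[0, 0]), float(arr.box[1, 1]))
        return AtomLattice(np.asarray(arr.coord, dtype=float), list(arr.element), cell=cell)
    if fmt == "XYZ":
        with open(path) as fh:
            n = int(fh.readline())
            fh.readline()
            els, pos = [], []
            for _ in range(n):
                parts = fh.readline().split()
                els.append(parts[0])
                pos.append([float(v) for v in parts[1:4]])
        return AtomLattice(np.array(pos).reshape(-1, 3), els, cell=(0.0, 0.0))
    raise ValueError(f"unsupported format {fmt!r}")
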