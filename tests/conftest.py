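"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

from graphsorb.energetics import ForceFieldParams
from graphsorb.lattice import AtomLattice, LatticeSpec, build_flat
from graphsorb.protein import ProteinModel
from graphsorb.system import BoxConditions, SimulationSystem
from graphsorb.synthetic import _bead_model, make_ideal_helix


@pytest.fixture(scope="session")
def small_lattice():
    """A ~30x30 Å, 3-layer graphite slab."""
    return build_flat(LatticeSpec(target_extent=(30.0, 30.0, 7.0)))


@pytest.fixture(scope="session")
def helix12():
    return make_ideal_helix(12)


@pytest.fixture()
def empty_lattice():
    return AtomLattice(np.empty((0, 3)), [], cell=(0.0, 0.0))


def bead_system(coords, lattice=None, box=None, internal=None, charges=None):
    """Assemble a SimulationSystem from raw bead coordinates."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    arr = _bead_model(coords, chain="A")
    if charges is not None:
        arr.charge = np.asarray(charges, dtype=float)
    model = ProteinModel(atoms=arr)
    if lattice is None:
        lattice = AtomLattice(np.empty((0, 3)), [], cell=(0.0, 0.0))
    if box is None:
        lx = lattice.cell[0] or 0.0
        ly = lattice.cell[1] or 0.0
        z_hi = max(coords[:, 2].max() + 50.0, lattice.z_top + 50.0) if len(coords) else 50.0
        box = BoxConditions(lx=lx, ly=ly, z_lo=min(-50.0, coords[:, 2].min() - 1.0), z_hi=z_hi)
    return SimulationSystem(protein=model, lattice=lattice, box=box,
                            ff=ForceFieldParams(), internal=internal)


@pytest.fixture()
def make_bead_system():
    return bead_system


def brute_force_adsorption(system, cutoff=12.0, sigma=3.195, depth=0.439):
    """Independent all-pairs double-loop oracle with x/y minimum image."""
    total = 0.0
    lx = system.box.lx or 1e12
    ly = system.box.ly or 1e12
    for p in system.protein.coords:
        for s in system.lattice.positions:
            dx = s[0] - p[0]
            dx -= round(dx / lx) * lx
            dy = s[1] - p[1]
            dy -= round(dy / ly) * ly
            dz = s[2] - p[2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r <= cutoff:
                sr6 = (sigma / r) ** 6
                total += 4.0 * depth * (sr6 * sr6 - sr6)
    return total
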