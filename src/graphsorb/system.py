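"""The assembled simulation system: protein + rigid substrate + box + force field."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class BoxConditions:
    """Periodic in x/y, hard reflective walls at z_lo/z_hi."""

    lx: float
    ly: float
    z_lo: float
    z_hi: float

    def __post_init__(self) -> None:
        if self.z_lo >= self.z_hi:
            raise ValueError("z_lo must be below z_hi")

    def wrap_xy(self, coords: np.ndarray) -> np.ndarray:
        out = np.array(coords, dtype=float)
        if self.lx > 0:
            out[:, 0] %= self.lx
        if self.ly > 0:
            out[:, 1] %= self.ly
        return out


@dataclass
class SimulationSystem:
    """Protein above a fixed substrate, with force-field and run parameters.

    ``internal`` optionally carries the protein's internal interaction
    model (bonds/angles/excluded volume) used by the simulator; the
    analysis modules only need coordinates, masses and charges.
    """

    protein: Any
    lattice: Any
    box: BoxConditions
    ff: Any
    internal: Any = None
    smd: Any = None
    metadata: dict = field(default_factory=dict)

    @property
    def min_gap(self) -> float:
        """Minimum vertical clearance between protein and substrate top."""
        return float(self.protein.coords[:, 2].min() - self.lattice.z_top)
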