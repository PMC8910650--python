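"""Desk-scale dynamics over a rigid Lennard-Jones substrate.

Protocol stages mirror the adsorption study workflow: energy
minimization, constant-velocity steered dynamics (a harmonic anchor
moving at velocity v pulls the backbone centroid toward the surface),
and Langevin relaxation at constant temperature.  The Langevin friction
and noise double as an implicit solvent; explicit water is deliberately
out of scope, which is the main fidelity gap relative to a full
solvated simulation (see docs/methods.md).

The protein's internal interactions are a configurable simplified
model: harmonic bonds and angles plus a 12-6 (or purely repulsive WCA)
excluded-volume term between non-bonded pairs.  The substrate is rigid:
its atoms never move and only exert the non-bonded surface force.

Boundary conditions: periodic in x/y (minimum image), reflective hard
walls at z_lo/z_hi.  Integration is BAOAB Langevin, which reduces to
velocity Verlet when the friction is zero.  All runs are exactly
reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from graphsorb.constants import AMU_TO_INTERNAL, KB
from graphsorb.conformation import Trajectory

__all__ = [
    "SMDParams",
    "ThermostatParams",
    "InternalModel",
    "minimize",
    "run_smd",
    "run_relaxation",
]


@dataclass(frozen=True)
class SMDParams:
    """Constant-velocity pulling parameters.

    Defaults follow the study protocol: spring constant
    k = 167.36 kJ/(mol Å²), pulling velocity v = 0.001 Å/ps, direction
    -z (toward the substrate), applied to the backbone atoms.
    """

    k: float = 167.36
    v: float = 0.001
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    pulled: tuple | None = None  # atom indices; None = backbone (N/CA/C), else all
    duration: float = 8.0  # ps
    mass_weighted: bool = False

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("spring constant must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        norm = float(np.linalg.norm(self.direction))
        if not np.isclose(norm, 1.0):
            raise ValueError("direction must be a unit vector")


@dataclass(frozen=True)
class ThermostatParams:
    """Langevin temperature control: target T, friction gamma, RNG seed."""

    T: float = 310.0
    gamma: float = 1.0  # ps^-1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.gamma < 0:
            raise ValueError("friction must be non-negative")


@dataclass
class InternalModel:
    """Simplified internal interactions for the mobile atoms.

    Harmonic bonds ``0.5 kb (r - b0)^2``, harmonic angles
    ``0.5 ka (theta - theta0)^2`` and a 12-6 excluded-volume term
    between pairs that are neither bonded nor 1-3 neighbours.  With
    ``wca=True`` the pair term is truncated and shifted at its minimum
    (purely repulsive).
    """

    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    bond_b0: np.ndarray = field(default_factory=lambda: np.empty(0))
    bond_k: np.ndarray = field(default_factory=lambda: np.empty(0))
    angles: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))
    angle_theta0: np.ndarray = field(default_factory=lambda: np.empty(0))
    angle_k: np.ndarray = field(default_factory=lambda: np.empty(0))
    nb_sigma: float = 4.0
    nb_epsilon: float = 0.3
    wca: bool = True
    n_atoms: int = 0

    _nb_pairs: np.ndarray | None = None

    def _nonbonded_pairs(self) -> np.ndarray:
        if self._nb_pairs is None:
            n = self.n_atoms
            iu = np.triu_indices(n, k=1)
            pairs = np.stack(iu, axis=1)
            excluded = set()
            for a, b in self.bonds:
                excluded.add((min(a, b), max(a, b)))
            adj: dict[int, set] = {}
            for a, b in self.bonds:
                adj.setdefault(int(a), set()).add(int(b))
                adj.setdefault(int(b), set()).add(int(a))
            for mid, nbrs in adj.items():
                for a in nbrs:
                    for b in nbrs:
                        if a < b:
                            excluded.add((a, b))
            keep = [k for k, (a, b) in enumerate(pairs) if (a, b) not in excluded]
            self._nb_pairs = pairs[keep]
        return self._nb_pairs

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        u = 0.0
        f = np.zeros_like(coords)

        if len(self.bonds):
            ab = coords[self.bonds[:, 1]] - coords[self.bonds[:, 0]]
            r = np.linalg.norm(ab, axis=1)
            dr = r - self.bond_b0
            u += float(np.sum(0.5 * self.bond_k * dr**2))
            fmag = (self.bond_k * dr / r)[:, None] * ab
            np.add.at(f, self.bonds[:, 0], fmag)
            np.add.at(f, self.bonds[:, 1], -fmag)

        if len(self.angles):
            i, j, k = self.angles.T
            rij = coords[i] - coords[j]
            rkj = coords[k] - coords[j]
            nij = np.linalg.norm(rij, axis=1)
            nkj = np.linalg.norm(rkj, axis=1)
            cos_t = np.clip(np.sum(rij * rkj, axis=1) / (nij * nkj), -1.0, 1.0)
            theta = np.arccos(cos_t)
            dtheta = theta - self.angle_theta0
            u += float(np.sum(0.5 * self.angle_k * dtheta**2))
            sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
            coef = self.angle_k * dtheta / sin_t
            di = (coef / nij)[:, None] * (rkj / nkj[:, None] - cos_t[:, None] * rij / nij[:, None])
            dk = (coef / nkj)[:, None] * (rij / nij[:, None] - cos_t[:, None] * rkj / nkj[:, None])
            np.add.at(f, i, di)
            np.add.at(f, k, dk)
            np.add.at(f, j, -(di + dk))

        pairs = self._nonbonded_pairs()
        if len(pairs) and self.nb_epsilon > 0:
            d = coords[pairs[:, 1]] - coords[pairs[:, 0]]
            r2 = np.sum(d * d, axis=1)
            cutoff2 = (2.0 ** (1.0 / 3.0)) * self.nb_sigma**2 if self.wca else (3.0 * self.nb_sigma) ** 2
            mask = r2 < cutoff2
            if np.any(mask):
                d = d[mask]
                r2m = r2[mask]
                sr6 = (self.nb_sigma**2 / r2m) ** 3
                e = 4.0 * self.nb_epsilon * (sr6 * sr6 - sr6)
                if self.wca:
                    e = e + self.nb_epsilon
                u += float(np.sum(e))
                coef = 24.0 * self.nb_epsilon * (2.0 * sr6 * sr6 - sr6) / r2m
                n = len(coords)
                for c in range(3):
                    w = coef * d[:, c]
                    f[:, c] += np.bincount(pairs[mask, 1], weights=w, minlength=n)
                    f[:, c] -= np.bincount(pairs[mask, 0], weights=w, minlength=n)

        return u, f


class SubstrateField:
    """Non-bonded force of the rigid substrate on mobile atoms.

    Uses a periodic KD-tree (x/y wrapped, z padded) with a Verlet-style
    neighbour list rebuilt whenever any atom has moved more than half
    the skin since the last build.
    """

    _Z_PAD = 1e6

    def __init__(self, lattice, box, ff, elements, skin: float = 2.0):
        self.box = box
        self.ff = ff
        self.cutoff = ff.cutoff
        self.skin = skin
        lx = box.lx if box.lx > 0 else self._Z_PAD
        ly = box.ly if box.ly > 0 else self._Z_PAD
        self.boxsize = np.array([lx, ly, self._Z_PAD])
        self.sub_raw = np.array(lattice.positions, dtype=float)
        sub = self.sub_raw.copy()
        if len(sub):
            sub[:, 0] %= lx
            sub[:, 1] %= ly
            sub[:, 2] += self._Z_PAD / 2.0
        self.sub = sub
        self.tree = cKDTree(sub, boxsize=self.boxsize) if len(sub) else None
        sig_dep = np.array([ff.lookup(e) for e in elements]) if len(elements) else np.empty((0, 2))
        self.sigma = sig_dep[:, 0] if len(sig_dep) else sig_dep
        self.depth = sig_dep[:, 1] if len(sig_dep) else sig_dep
        self._ref = None
        self._ai = np.empty(0, dtype=int)
        self._si = np.empty(0, dtype=int)

    def _wrap(self, coords: np.ndarray) -> np.ndarray:
        pos = np.array(coords, dtype=float)
        pos[:, 0] %= self.boxsize[0]
        pos[:, 1] %= self.boxsize[1]
        pos[:, 2] += self._Z_PAD / 2.0
        return pos

    def _rebuild(self, coords: np.ndarray) -> None:
        pos = self._wrap(coords)
        lists = self.tree.query_ball_point(pos, self.cutoff + self.skin)
        ai, si = [], []
        for i, idx in enumerate(lists):
            ai.extend([i] * len(idx))
            si.extend(idx)
        self._ai = np.array(ai, dtype=int)
        self._si = np.array(si, dtype=int)
        # substrate coords in original (unwrapped-z) frame for fast min-image
        self._sub_sel = self.sub_raw[self._si] if len(self._si) else np.empty((0, 3))
        self._sig2 = self.sigma[self._ai] ** 2 if len(self._ai) else np.empty(0)
        self._dep = self.depth[self._ai] if len(self._ai) else np.empty(0)
        self._ref = np.array(coords, dtype=float)

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        f = np.zeros_like(coords)
        if self.tree is None:
            return 0.0, f
        if self._ref is None or np.max(np.abs(coords - self._ref)) > self.skin / 2.0:
            self._rebuild(coords)
        if not len(self._ai):
            return 0.0, f
        d = self._sub_sel - coords[self._ai]
        # minimum image in the periodic x/y directions only
        lx, ly = self.boxsize[0], self.boxsize[1]
        d[:, 0] -= np.rint(d[:, 0] / lx) * lx
        d[:, 1] -= np.rint(d[:, 1] / ly) * ly
        r2 = np.einsum("ij,ij->i", d, d)
        mask = r2 <= self.cutoff**2
        if not np.any(mask):
            return 0.0, f
        ai = self._ai[mask]
        d = d[mask]
        r2 = r2[mask]
        sr6 = (self._sig2[mask] / r2) ** 3
        dep = self._dep[mask]
        u = float(np.sum(4.0 * dep * (sr6 * sr6 - sr6)))
        # force on the mobile atom: -dU/dr along (r_atom - r_sub) = -d
        coef = -24.0 * dep * (2.0 * sr6 * sr6 - sr6) / r2
        n = len(coords)
        for c in range(3):
            f[:, c] += np.bincount(ai, weights=coef * d[:, c], minlength=n)
        return u, f


def _system_field(system) -> SubstrateField:
    key = "_substrate_field"
    fld = system.metadata.get(key)
    if fld is None:
        fld = SubstrateField(system.lattice, system.box, system.ff,
                             list(system.protein.atoms.element))
        system.metadata[key] = fld
    return fld


def _total_energy_forces(system, coords: np.ndarray) -> tuple[float, np.ndarray]:
    u_sub, f_sub = _system_field(system).energy_forces(coords)
    if system.internal is not None:
        u_int, f_int = system.internal.energy_forces(coords)
    else:
        u_int, f_int = 0.0, np.zeros_like(coords)
    return u_sub + u_int, f_sub + f_int


def _backbone_or_all(system) -> np.ndarray:
    names = system.protein.atoms.atom_name
    bb = np.flatnonzero(np.isin(names, ("N", "CA", "C")))
    return bb if len(bb) else np.arange(system.protein.n_atoms)


def minimize(system, max_steps: int = 500, force_tol: float = 10.0):
    """Minimise the potential energy of the mobile atoms (L-BFGS).

    Deterministic for a fixed input; terminates when the maximum force
    component falls below ``force_tol`` (kJ/mol/Å) or at ``max_steps``.
    Returns a new system; the input is untouched.
    """
    from scipy.optimize import minimize as scipy_minimize

    x0 = system.protein.coords
    u0, _ = _total_energy_forces(system, x0)
    if not np.isfinite(u0):
        raise ValueError("non-finite initial energy; check starting geometry")

    shape = x0.shape

    def fun(x):
        u, f = _total_energy_forces(system, x.reshape(shape))
        return u, -f.ravel()

    res = scipy_minimize(fun, x0.ravel(), jac=True, method="L-BFGS-B",
                         options={"maxiter": max_steps, "gtol": force_tol,
                                  "ftol": 1e-14})
    out = _clone_system(system)
    xmin = res.x.reshape(shape)
    umin = float(res.fun)
    if umin > u0:  # L-BFGS never accepts an uphill result, but guard anyway
        xmin, umin = x0, u0
    out.protein.coords = xmin
    out.metadata["minimize"] = {"initial_energy": float(u0), "final_energy": umin,
                                "n_iter": int(res.nit)}
    return out


def _clone_system(system):
    from graphsorb.system import SimulationSystem

    return SimulationSystem(
        protein=system.protein.copy(),
        lattice=system.lattice,
        box=system.box,
        ff=system.ff,
        internal=system.internal,
        smd=system.smd,
        metadata={k: v for k, v in system.metadata.items() if not k.startswith("_")},
    )


def _apply_walls(x: np.ndarray, v: np.ndarray, box) -> None:
    """Reflect positions/velocities at the z hard walls, in place."""
    z = x[:, 2]
    zmin, zmax = z.min(), z.max()
    if zmin >= box.z_lo and zmax <= box.z_hi:
        return
    for _ in range(2):
        high = x[:, 2] > box.z_hi
        x[high, 2] = 2.0 * box.z_hi - x[high, 2]
        v[high, 2] *= -1.0
        low = x[:, 2] < box.z_lo
        x[low, 2] = 2.0 * box.z_lo - x[low, 2]
        v[low, 2] *= -1.0
        if not (np.any(x[:, 2] > box.z_hi) or np.any(x[:, 2] < box.z_lo)):
            return
    raise RuntimeError("particle crossed both z walls in one step; reduce dt")


def _integrate(system, duration: float, thermo: ThermostatParams, dt: float,
               stride: int, smd: SMDParams | None, fixed_indices=None):
    """BAOAB Langevin integration; returns (Trajectory, log DataFrame)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = max(1, int(round(duration / dt)))
    prot = system.protein
    x = prot.coords.copy()
    m = prot.masses * AMU_TO_INTERNAL
    inv_m = 1.0 / m[:, None]
    rng = np.random.default_rng(thermo.seed)

    fixed = np.zeros(len(x), dtype=bool)
    if fixed_indices is not None:
        fixed[np.asarray(fixed_indices, dtype=int)] = True

    pulled = None
    if smd is not None:
        pulled = (np.asarray(smd.pulled, dtype=int) if smd.pulled is not None
                  else _backbone_or_all(system))
        if np.any(fixed[pulled]) and smd.pulled is not None:
            raise ValueError("pulled atoms must not be fixed")
        direction = np.asarray(smd.direction, dtype=float)
        if smd.mass_weighted:
            w = m[pulled] / m[pulled].sum()
        else:
            w = np.full(len(pulled), 1.0 / len(pulled))
        anchor0 = x[pulled].mean(axis=0)

    # Maxwell-Boltzmann start
    v = rng.normal(0.0, np.sqrt(KB * thermo.T / m)[:, None], size=x.shape)
    v[fixed] = 0.0

    c1 = np.exp(-thermo.gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    noise_scale = np.sqrt(KB * thermo.T / m)[:, None]

    def add_smd(forces, t):
        anchor = anchor0 + smd.v * t * direction
        centroid = x[pulled].mean(axis=0)
        f_spring = smd.k * (anchor - centroid)
        forces[pulled] += w[:, None] * f_spring  # distributed spring force
        return float(np.dot(f_spring, direction))

    u, f = _total_energy_forces(system, x)
    t = 0.0
    if smd is not None:
        add_smd(f, t)

    frames = [x.copy()]
    times = [0.0]
    log_rows = []
    work = 0.0

    def log_state(step, t, u, f_pull):
        ke = 0.5 * float(np.sum(m[:, None] * v * v))
        n_free = int((~fixed).sum())
        temp = 2.0 * ke / (3.0 * max(n_free, 1) * KB)
        log_rows.append({"time": t, "potential": u, "kinetic": ke,
                         "total": u + ke, "temperature": temp,
                         "smd_force": f_pull, "smd_work": work})

    f_pull0 = 0.0 if smd is None else smd.k * 0.0
    log_state(0, 0.0, u, f_pull0)

    for step in range(1, n_steps + 1):
        v += 0.5 * dt * f * inv_m
        v[fixed] = 0.0
        x += 0.5 * dt * v
        _apply_walls(x, v, system.box)
        if thermo.gamma > 0:
            v = c1 * v + c2 * noise_scale * rng.standard_normal(x.shape)
            v[fixed] = 0.0
        x += 0.5 * dt * v
        _apply_walls(x, v, system.box)
        t = step * dt
        u, f = _total_energy_forces(system, x)
        f_pull = 0.0
        if smd is not None:
            f_pull = add_smd(f, t)
            work += f_pull * smd.v * dt
        v += 0.5 * dt * f * inv_m
        v[fixed] = 0.0

        if step % stride == 0 or step == n_steps:
            frames.append(x.copy())
            times.append(t)
            log_state(step, t, u, f_pull)

    prot_out = _clone_system(system)
    prot_out.protein.coords = x
    traj = Trajectory(np.array(frames), np.array(times),
                      meta={"dt": dt, "stride": stride, "seed": thermo.seed,
                            "gamma": thermo.gamma, "T": thermo.T,
                            "smd": smd, "duration": duration})
    return prot_out, traj, pd.DataFrame(log_rows)


def run_smd(system, smd: SMDParams | None = None,
            thermo: ThermostatParams | None = None,
            dt: float = 0.002, stride: int = 100, fixed_indices=None):
    """Constant-velocity steered dynamics.

    The harmonic anchor starts at the pulled-set centroid and moves at
    ``smd.v`` along ``smd.direction``; the spring force
    ``k (anchor - centroid)`` is distributed over the pulled atoms.
    Returns (final system, trajectory, force/work/energy log).
    """
    smd = smd if smd is not None else SMDParams()
    thermo = thermo if thermo is not None else ThermostatParams()
    return _integrate(system, smd.duration, thermo, dt, stride, smd, fixed_indices)


def run_relaxation(system, duration: float = 20.0,
                   thermo: ThermostatParams | None = None,
                   dt: float = 0.002, stride: int = 100, fixed_indices=None):
    """Langevin relaxation (no pulling). Returns (system, trajectory, log)."""
    thermo = thermo if thermo is not None else ThermostatParams()
    return _integrate(system, duration, thermo, dt, stride, None, fixed_indices)
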