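"""Minimization, steered dynamics and Langevin relaxation."""

import numpy as np
import pytest

from graphsorb.simulate import (
    InternalModel,
    SMDParams,
    ThermostatParams,
    _apply_walls,
    minimize,
    run_relaxation,
    run_smd,
)
from graphsorb.system import BoxConditions
from tests.conftest import bead_system

SIGMA = 3.195
DEPTH = 0.439
R_MIN = 2.0 ** (1.0 / 6.0) * SIGMA


def lj_dimer(r0):
    internal = InternalModel(nb_sigma=SIGMA, nb_epsilon=DEPTH, wca=False, n_atoms=2)
    return bead_system([[0, 0, 0], [0, 0, r0]], internal=internal)


class TestMinimize:
    def test_lj_dimer_converges_to_analytic_minimum(self):
        out = minimize(lj_dimer(3.0), force_tol=1e-8)
        r = np.linalg.norm(np.diff(out.protein.coords, axis=0))
        assert r == pytest.approx(R_MIN, abs=1e-3)
        assert out.metadata["minimize"]["final_energy"] == pytest.approx(-DEPTH, abs=1e-6)

    def test_already_minimal_system_is_fixed_point(self):
        first = minimize(lj_dimer(3.2), force_tol=1e-10)
        second = minimize(first, force_tol=1e-10)
        e1 = first.metadata["minimize"]["final_energy"]
        e2 = second.metadata["minimize"]["final_energy"]
        assert e2 == pytest.approx(e1, abs=1e-10)
        assert e2 <= e1 + 1e-12

    def test_harmonic_dimer_reaches_rest_length(self):
        internal = InternalModel(bonds=np.array([[0, 1]]), bond_b0=np.array([4.2]),
                                 bond_k=np.array([300.0]), nb_epsilon=0.0, n_atoms=2)
        system = bead_system([[0, 0, 0], [0, 0, 3.0]], internal=internal)
        out = minimize(system, force_tol=1e-10)
        r = np.linalg.norm(np.diff(out.protein.coords, axis=0))
        assert r == pytest.approx(4.2, abs=1e-6)

    def test_energy_never_increases(self):
        system = lj_dimer(2.8)
        out = minimize(system)
        info = out.metadata["minimize"]
        assert info["final_energy"] <= info["initial_energy"]


class TestIntegration:
    def test_nve_energy_conservation(self):
        """gamma = 0 (velocity-Verlet limit): relative drift < 1e-4 over 1e4 steps."""
        system = minimize(lj_dimer(3.2), force_tol=1e-10)
        thermo = ThermostatParams(T=30.0, gamma=0.0, seed=42)
        _, _, log = run_relaxation(system, duration=10.0, thermo=thermo,
                                   dt=0.001, stride=100)
        total = log["total"].to_numpy()
        drift = np.max(np.abs(total - total[0])) / abs(total[0])
        assert drift < 1e-4

    def test_langevin_temperature_on_ideal_beads(self):
        """Equipartition: mean kinetic temperature within 3% of 310 K."""
        rng = np.random.default_rng(0)
        coords = rng.uniform(5, 45, size=(400, 3))
        internal = InternalModel(nb_epsilon=0.0, n_atoms=400)
        system = bead_system(coords, internal=internal,
                             box=BoxConditions(50.0, 50.0, 0.0, 60.0))
        system.protein.coords = np.clip(coords, 6, 44)
        thermo = ThermostatParams(T=310.0, gamma=2.0, seed=9)
        _, _, log = run_relaxation(system, duration=20.0, thermo=thermo,
                                   dt=0.005, stride=50)
        mean_T = log["temperature"].iloc[5:].mean()
        assert mean_T == pytest.approx(310.0, rel=0.03)

    def test_wall_reflection_preserves_speed(self):
        x = np.array([[1.0, 1.0, 59.5], [1.0, 1.0, -0.7]])
        v = np.array([[0.0, 0.0, 3.0], [0.0, 0.0, -2.0]])
        box = BoxConditions(10.0, 10.0, 0.0, 59.0)
        _apply_walls(x, v, box)
        assert x[0, 2] == pytest.approx(58.5)
        assert v[0, 2] == -3.0
        assert x[1, 2] == pytest.approx(0.7)
        assert v[1, 2] == 2.0

    def test_wall_double_crossing_is_error(self):
        x = np.array([[0.0, 0.0, 500.0]])
        v = np.array([[0.0, 0.0, 1.0]])
        with pytest.raises(RuntimeError, match="reduce dt"):
            _apply_walls(x, v, BoxConditions(10.0, 10.0, 0.0, 5.0))

    def test_substrate_force_periodic_in_xy(self, small_lattice):
        """An atom leaving +x re-enters at -x: the field is periodic."""
        from graphsorb.simulate import SubstrateField
        from graphsorb.energetics import ForceFieldParams

        box = BoxConditions(small_lattice.cell[0], small_lattice.cell[1], 0.0, 50.0)
        z = small_lattice.z_top + 3.5
        p = np.array([[3.3, 7.7, z]])
        field = SubstrateField(small_lattice, box, ForceFieldParams(), ["C"])
        u0, f0 = field.energy_forces(p)
        field2 = SubstrateField(small_lattice, box, ForceFieldParams(), ["C"])
        u1, f1 = field2.energy_forces(p + [small_lattice.cell[0], 0.0, 0.0])
        assert u1 == pytest.approx(u0, abs=1e-8)
        assert np.allclose(f0, f1, atol=1e-8)

    def test_dt_must_be_positive(self):
        with pytest.raises(ValueError):
            run_relaxation(lj_dimer(3.2), duration=1.0, dt=0.0)


class TestSMD:
    def test_pinned_atom_logs_spring_force_kvt(self):
        """With the pulled atom held fixed the logged force is exactly k v t."""
        internal = InternalModel(nb_epsilon=0.0, n_atoms=1)
        system = bead_system([[5.0, 5.0, 30.0]], internal=internal)
        smd = SMDParams(k=167.36, v=0.001, duration=10.0)
        _, _, log = run_smd(system, smd, ThermostatParams(seed=1), dt=0.002,
                            stride=500, fixed_indices=[0])
        t = log["time"].to_numpy()[1:]
        f = log["smd_force"].to_numpy()[1:]
        assert np.allclose(f, 167.36 * 0.001 * t, rtol=1e-12)

    def test_zero_velocity_reduces_to_positional_restraint(self):
        internal = InternalModel(nb_epsilon=0.0, n_atoms=1)
        system = bead_system([[5.0, 5.0, 30.0]], internal=internal)
        smd = SMDParams(k=167.36, v=0.0, duration=20.0)
        _, traj, _ = run_smd(system, smd, ThermostatParams(seed=2), dt=0.002, stride=200)
        z = traj.frames[:, 0, 2]
        # centroid fluctuates about the (static) anchor
        assert abs(z.mean() - 30.0) < 0.5
        assert z.std() < 1.0

    def test_work_non_negative_against_repulsive_barrier(self):
        """Pulling a bead into a purely repulsive (WCA) partner costs work."""
        internal = InternalModel(nb_sigma=4.0, nb_epsilon=1.0, wca=True, n_atoms=2)
        system = bead_system([[5.0, 5.0, 10.0], [5.0, 5.0, 18.0]], internal=internal)
        smd = SMDParams(k=200.0, v=0.05, duration=40.0,
                        direction=(0.0, 0.0, -1.0), pulled=(1,))
        _, _, log = run_smd(system, smd, ThermostatParams(T=50.0, gamma=1.0, seed=3),
                            dt=0.002, stride=500, fixed_indices=[0])
        assert log["smd_work"].iloc[-1] > 0.0

    def test_pulled_and_fixed_overlap_is_error(self):
        internal = InternalModel(nb_epsilon=0.0, n_atoms=2)
        system = bead_system([[0, 0, 10], [0, 0, 14]], internal=internal)
        smd = SMDParams(duration=1.0, pulled=(0,))
        with pytest.raises(ValueError, match="fixed"):
            run_smd(system, smd, ThermostatParams(seed=0), dt=0.002, fixed_indices=[0])


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_lattice):
        from graphsorb.synthetic import make_toy_dimer_system

        runs = []
        for _ in range(2):
            system = make_toy_dimer_system("flat", n_per_chain=8, seed=5)
            thermo = ThermostatParams(T=310.0, gamma=1.0, seed=5)
            _, traj, _ = run_relaxation(system, duration=1.0, thermo=thermo,
                                        dt=0.002, stride=100)
            runs.append(traj.frames)
        assert np.array_equal(runs[0], runs[1])

    def test_different_seed_differs(self):
        from graphsorb.synthetic import make_toy_dimer_system

        frames = []
        for seed in (1, 2):
            system = make_toy_dimer_system("flat", n_per_chain=8, seed=1)
            thermo = ThermostatParams(T=310.0, gamma=1.0, seed=seed)
            _, traj, _ = run_relaxation(system, duration=1.0, thermo=thermo,
                                        dt=0.002, stride=100)
            frames.append(traj.frames)
        assert not np.array_equal(frames[0], frames[1])

    def test_substrate_never_moves(self):
        from graphsorb.synthetic import make_toy_dimer_system

        system = make_toy_dimer_system("SQ", n_per_chain=8, seed=0)
        before = system.lattice.positions.copy()
        out, _, _ = run_relaxation(system, duration=1.0,
                                   thermo=ThermostatParams(seed=0), dt=0.002)
        assert np.array_equal(out.lattice.positions, before)
        assert np.array_equal(system.lattice.positions, before)
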