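"""Trajectory metrics: RMSD, Rg, dihedrals, Ramachandran, secondary structure."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from graphsorb.conformation import (
    Trajectory,
    assign_secondary_structure,
    backbone_dihedrals,
    dihedral,
    load_region_map,
    radius_of_gyration,
    ramachandran_classify,
    rg_series,
    rmsd,
    ss_content_table,
)
from graphsorb.synthetic import make_beta_hairpin, make_extended_chain, make_ideal_helix


class TestRMSD:
    def test_identity_is_zero(self):
        frame = np.random.default_rng(0).normal(size=(10, 3))
        traj = Trajectory(np.stack([frame, frame]), [0.0, 1.0])
        assert rmsd(traj)[1] == 0.0

    def test_uniform_translation_by_3_4_0_gives_5(self):
        frame = np.random.default_rng(1).normal(size=(7, 3))
        traj = Trajectory(np.stack([frame, frame + [3.0, 4.0, 0.0]]), [0.0, 1.0])
        assert rmsd(traj)[1] == pytest.approx(5.0, abs=1e-12)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(size=(5, 10, 3))
        traj = Trajectory(frames, np.arange(5.0))
        got = rmsd(traj)
        ref = frames[0]
        expected = [np.sqrt(np.sum((f - ref) ** 2) / 10) for f in frames]
        assert np.allclose(got, expected, atol=1e-12)
        assert rmsd(traj, mode="time_averaged") == pytest.approx(np.mean(expected), abs=1e-12)

    def test_single_frame_series(self):
        traj = Trajectory(np.zeros((1, 4, 3)), [0.0])
        out = rmsd(traj)
        assert len(out) == 1 and out[0] == 0.0

    def test_pure_rotation_is_not_invariant_without_fit(self):
        """The lab frame is substrate-fixed: rotation about the COM counts."""
        rng = np.random.default_rng(3)
        frame = rng.normal(size=(12, 3))
        com = frame.mean(axis=0)
        rot = Rotation.from_euler("z", 30, degrees=True)
        rotated = rot.apply(frame - com) + com
        traj = Trajectory(np.stack([frame, rotated]), [0.0, 1.0])
        assert rmsd(traj)[1] > 0.1
        assert rmsd(traj, superpose=True)[1] == pytest.approx(0.0, abs=1e-6)


class TestRadiusOfGyration:
    def test_point_mass_zero(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]], [12.0]) == 0.0

    def test_two_unit_masses_give_half_separation(self):
        d = 7.3
        rg = radius_of_gyration([[0, 0, 0], [d, 0, 0]], [1.0, 1.0])
        assert rg == pytest.approx(d / 2.0, abs=1e-12)

    def test_ring_of_equal_masses_gives_radius(self):
        theta = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        R = 4.2
        coords = np.column_stack([R * np.cos(theta), R * np.sin(theta), np.zeros(36)])
        assert radius_of_gyration(coords, np.ones(36)) == pytest.approx(R, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(20, 3))
        masses = rng.uniform(1, 20, size=20)
        rg0 = radius_of_gyration(coords, masses)
        moved = Rotation.random(random_state=1).apply(coords) + [5.0, -3.0, 8.0]
        assert radius_of_gyration(moved, masses) == pytest.approx(rg0, abs=1e-9)

    def test_zero_mass_error(self):
        with pytest.raises(ValueError):
            radius_of_gyration([[0, 0, 0]], [0.0])

    def test_series_over_trajectory(self):
        frames = np.stack([np.eye(3), 2 * np.eye(3)])
        out = rg_series(Trajectory(frames, [0.0, 1.0]), np.ones(3))
        assert out[1] == pytest.approx(2 * out[0], abs=1e-12)


class TestDihedrals:
    def test_planar_trans_is_180(self):
        p = [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]]
        assert dihedral(*p) == pytest.approx(180.0, abs=1e-9)

    def test_helix_construct_then_measure_round_trip(self, helix12):
        df = backbone_dihedrals(helix12)
        interior = df.iloc[1:-1]
        assert np.allclose(interior["phi"], -57.0, atol=0.5)
        assert np.allclose(interior["psi"], -47.0, atol=0.5)
        assert np.isnan(df["phi"].iloc[0]) and np.isnan(df["psi"].iloc[-1])

    def test_mirror_image_negates_dihedrals(self, helix12):
        df0 = backbone_dihedrals(helix12)
        mirrored = helix12.copy()
        mirrored.coords = mirrored.coords * np.array([1.0, 1.0, -1.0])
        df1 = backbone_dihedrals(mirrored)
        ok = df0["phi"].notna()
        assert np.allclose(df1["phi"][ok], -df0["phi"][ok], atol=1e-6)

    def test_invariant_under_global_rigid_motion(self, helix12):
        df0 = backbone_dihedrals(helix12)
        moved = helix12.copy()
        moved.coords = Rotation.random(random_state=7).apply(moved.coords) + [3.0, 4.0, 5.0]
        df1 = backbone_dihedrals(moved)
        ok = df0["phi"].notna()
        assert np.allclose(df0["phi"][ok], df1["phi"][ok], atol=1e-9)
        ok = df0["psi"].notna()
        assert np.allclose(df0["psi"][ok], df1["psi"][ok], atol=1e-9)


class TestRamachandran:
    def test_canonical_helix_point_is_favored(self):
        assert ramachandran_classify(-60.0, -45.0)[0] == "favored"

    def test_far_point_is_disallowed(self):
        assert ramachandran_classify(60.0, -170.0)[0] == "disallowed"

    def test_nan_is_undefined(self):
        assert ramachandran_classify(np.nan, 100.0)[0] == "undefined"

    def test_classification_matches_point_in_polygon_oracle(self):
        from shapely.geometry import Point, Polygon

        region_map = load_region_map()
        rng = np.random.default_rng(5)
        phi = rng.uniform(-180, 180, size=1000)
        psi = rng.uniform(-180, 180, size=1000)
        got = ramachandran_classify(phi, psi, region_map)
        favored = [Polygon(p) for p in region_map["favored"].values()]
        allowed = [Polygon(p) for p in region_map["allowed"].values()]
        for x, y, label in zip(phi, psi, got):
            pt = Point(x, y)
            if any(poly.contains(pt) for poly in favored):
                expected = "favored"
            elif any(poly.contains(pt) for poly in allowed):
                expected = "allowed"
            else:
                expected = "disallowed"
            assert label == expected

    def test_pure_function_of_inputs(self):
        a = ramachandran_classify([-60, 100], [-45, 100])
        b = ramachandran_classify([-60, 100], [-45, 100])
        assert list(a) == list(b)


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_alpha(self, helix12):
        df = assign_secondary_structure(helix12)
        ss = "".join(df["ss"])
        assert "HHHH" in ss
        content = ss_content_table(df)
        assert content.loc["alpha_helix", "A"] >= 66.0

    def test_extended_chain_has_no_helix_or_sheet(self):
        df = assign_secondary_structure(make_extended_chain(12))
        assert set(df["ss"]) == {"C"}

    def test_beta_hairpin_detects_strands(self):
        df = assign_secondary_structure(make_beta_hairpin(6))
        assert (df["ss"] == "E").sum() >= 6
        assert (df["ss"] == "H").sum() == 0

    def test_short_chain_cannot_be_helix(self):
        df = assign_secondary_structure(make_ideal_helix(4))
        assert "H" not in set(df["ss"])

    def test_content_sums_to_100_with_other(self, helix12):
        table = ss_content_table(assign_secondary_structure(helix12))
        assert table["A"].sum() == pytest.approx(100.0, abs=0.02)

    def test_agrees_with_independent_dssp_on_helix(self, tmp_path):
        """Cross-check against mdtraj's DSSP implementation."""
        mdtraj = pytest.importorskip("mdtraj")
        helix = make_ideal_helix(14)
        path = tmp_path / "helix.pdb"
        helix.write_pdb(path)
        t = mdtraj.load(str(path))
        ref = mdtraj.compute_dssp(t, simplified=True)[0]
        ours = assign_secondary_structure(helix)["ss"].to_numpy()
        ours_h = ours == "H"
        ref_h = ref == "H"
        # per-element boundaries may differ by one residue per end
        assert abs(int(ours_h.sum()) - int(ref_h.sum())) <= 2
        assert (ours_h & ref_h).sum() >= min(ours_h.sum(), ref_h.sum()) - 2


class TestTrajectoryContainer:
    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            Trajectory(np.zeros((2, 3, 3)), [1.0, 1.0])

    def test_frame_count_must_match_times(self):
        with pytest.raises(ValueError):
            Trajectory(np.zeros((2, 3, 3)), [0.0])

    def test_xyz_round_trip(self, tmp_path):
        frames = np.random.default_rng(0).normal(size=(3, 5, 3))
        traj = Trajectory(frames, [0.0, 1.0, 2.0])
        path = tmp_path / "t.xyz"
        traj.write_xyz(path)
        from graphsorb.cli import _read_xyz_frames

        back, times = _read_xyz_frames(path)
        assert np.allclose(back, frames, atol=1e-6)
        assert np.allclose(times, [0.0, 1.0, 2.0])
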