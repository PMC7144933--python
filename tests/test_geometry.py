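import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chromkit import core_io, geometry
from chromkit.core_io import Atom, AtomSelection, StructureFrame
from chromkit.errors import (
    DegenerateGeometryError,
    ParameterError,
    SelectionEmptyError,
    StructuralMismatchError,
)
from chromkit.geometry import (
    LinkerArmSpec,
    PlaneSpec,
    compute_linker_angles,
    compute_phi_angles,
    contact_table,
    define_nucleosomal_plane,
    end_to_end_distance,
    rmsd,
    vector_angle,
)
from chromkit.synthetic_data import ToyChromatosomeParams, make_toy_chromatosome

from conftest import arm_spec_from_truth, make_trajectory, plane_spec_from_truth


def sel(*indices):
    return AtomSelection("manual", np.array(indices, dtype=int))


class TestVectorAngle:
    def test_parallel(self):
        assert vector_angle([1, 0, 0], [1, 0, 0]) == 0.0

    def test_orthogonal(self):
        assert vector_angle([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_random_pairs_match_acos_oracle(self, rng):
        for _ in range(1000):
            u, v = rng.normal(size=3), rng.normal(size=3)
            cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            expected = math.degrees(math.acos(max(-1.0, min(1.0, cos))))
            assert vector_angle(u, v) == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_errors(self):
        with pytest.raises(DegenerateGeometryError):
            vector_angle([0, 0, 0], [1, 0, 0])


class TestPhiAngles:
    @staticmethod
    def _build(loop_dir):
        """alpha1 along z, beta_sheet along x, alpha3 at origin, loop at dir."""
        coords = []
        # alpha1: 4 atoms along z far away; beta_sheet: 4 atoms along x
        for k in range(4):
            coords.append([20.0, 0.0, float(k)])  # alpha1
        for k in range(4):
            coords.append([float(k), 20.0, 0.0])  # beta_sheet
        for k in range(3):
            coords.append([0.0, 0.0, 0.0])  # alpha3 cluster at origin
        loop = 10.0 * np.asarray(loop_dir, float)
        for k in range(3):
            coords.append(loop)  # beta_loop cluster
        traj = make_trajectory(np.asarray(coords)[None, :, :])
        groups = {
            "alpha1": sel(0, 1, 2, 3),
            "beta_sheet": sel(4, 5, 6, 7),
            "alpha3": sel(8, 9, 10),
            "beta_loop": sel(11, 12, 13),
        }
        return traj, groups

    def test_loop_parallel_to_sheet_axis_gives_phi2_zero(self):
        traj, groups = self._build([1, 0, 0])
        _, phi2 = compute_phi_angles(traj, groups)
        assert phi2.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_loop_perpendicular_to_alpha1_gives_phi1_ninety(self):
        traj, groups = self._build([1, 0, 0])
        phi1, _ = compute_phi_angles(traj, groups)
        assert phi1.values[0] == pytest.approx(90.0, abs=1e-9)

    def test_constructed_526_degrees(self):
        a = math.radians(52.6)
        traj, groups = self._build([math.cos(a), 0.0, math.sin(a)])
        _, phi2 = compute_phi_angles(traj, groups)
        assert phi2.values[0] == pytest.approx(52.6, abs=1e-6)

    def test_small_group_errors(self):
        traj, groups = self._build([1, 0, 0])
        groups["alpha1"] = sel(0, 1)
        with pytest.raises(DegenerateGeometryError):
            compute_phi_angles(traj, groups)


def _square_plane_frame():
    """C1'-labeled atoms on z=0: two quadrant clusters plus a dyad pair."""
    atoms = [Atom("C1'", "C", i + 1, "DA", "DNA") for i in range(6)]
    coords = np.array(
        [
            [10.0, 0.0, 0.0],
            [10.0, 2.0, 0.0],  # quadrant a
            [0.0, 10.0, 0.0],
            [2.0, 10.0, 0.0],  # quadrant b
            [-5.0, -5.0, 0.0],
            [-5.0, -4.0, 0.0],  # dyad pair
        ]
    )
    frame = StructureFrame(atoms, coords)
    spec = PlaneSpec(sel(0, 1), sel(2, 3), sel(4, 5))
    return frame, spec


class TestNucleosomalPlane:
    def test_planar_atoms_give_z_normal(self):
        frame, spec = _square_plane_frame()
        plane = define_nucleosomal_plane(frame.coords, spec)
        assert abs(np.dot(plane.normal, [0, 0, 1])) == pytest.approx(1.0)

    def test_constructed_quadrants_unit_z(self):
        atoms = [Atom("C1'", "C", i + 1, "DA", "DNA") for i in range(3)]
        coords = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 0]])
        spec = PlaneSpec(sel(0), sel(1), sel(2))
        plane = define_nucleosomal_plane(coords, spec)
        np.testing.assert_allclose(np.abs(plane.normal), [0, 0, 1], atol=1e-12)

    def test_rotation_equivariance(self, rng):
        frame, spec = _square_plane_frame()
        base = define_nucleosomal_plane(frame.coords, spec)
        rot = Rotation.random(random_state=5).as_matrix()
        rotated = define_nucleosomal_plane(frame.coords @ rot.T, spec)
        np.testing.assert_allclose(rotated.normal, rot @ base.normal, atol=1e-9)

    def test_collinear_errors(self):
        atoms = [Atom("C1'", "C", i + 1, "DA", "DNA") for i in range(3)]
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            define_nucleosomal_plane(coords, PlaneSpec(sel(0), sel(1), sel(2)))

    def test_normal_points_away_from_core(self):
        frame, spec = _square_plane_frame()
        atoms = frame.atoms + [Atom("CA", "C", 100, "ALA", "CORE")]
        coords = np.vstack([frame.coords, [[0.0, 0.0, -8.0]]])
        spec = PlaneSpec(spec.quadrant_a, spec.quadrant_b, spec.dyad_pair, sel(6))
        plane = define_nucleosomal_plane(StructureFrame(atoms, coords).coords, spec)
        assert plane.normal[2] == pytest.approx(1.0)


class TestLinkerAngles:
    @staticmethod
    def _chromatosome(**kwargs):
        params = ToyChromatosomeParams(**kwargs)
        traj, truth = make_toy_chromatosome(params)
        plane = plane_spec_from_truth(traj.topology, truth)
        return traj, truth, plane

    def test_in_plane_arm_beta_zero(self):
        traj, truth, plane = self._chromatosome(beta_entry=0.0, alpha_entry=15.0)
        arm = arm_spec_from_truth(traj.topology, truth, "entry")
        _, beta = compute_linker_angles(traj, plane, arm)
        assert beta.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_arm_along_normal_beta_90_alpha_nan(self):
        traj, truth, plane = self._chromatosome()
        arm = arm_spec_from_truth(traj.topology, truth, "entry")
        io = arm.origin_selection.indices
        it = arm.terminal_selection.indices
        frames = traj.frames.copy()
        origin_com = frames[0, io].mean(axis=0)
        shift = origin_com + np.array([0, 0, 30.0]) - frames[0, it].mean(axis=0)
        frames[0, it] += shift
        traj2 = core_io.Trajectory(traj.topology, frames)
        alpha, beta = compute_linker_angles(traj2, plane, arm)
        assert beta.values[0] == pytest.approx(90.0, abs=1e-6)
        assert np.isnan(alpha.values[0])

    def test_generator_round_trip(self):
        traj, truth, plane = self._chromatosome(alpha_entry=25.0, beta_exit=-10.0)
        for side in ("entry", "exit"):
            arm = arm_spec_from_truth(traj.topology, truth, side)
            alpha, beta = compute_linker_angles(traj, plane, arm)
            assert alpha.values[0] == pytest.approx(truth[f"alpha_{side}"], abs=0.5)
            assert beta.values[0] == pytest.approx(truth[f"beta_{side}"], abs=0.5)

    def test_mirror_through_plane_flips_beta(self):
        traj, truth, plane = self._chromatosome(beta_entry=20.0, alpha_entry=10.0)
        arm = arm_spec_from_truth(traj.topology, truth, "entry")
        _, beta_up = compute_linker_angles(traj, plane, arm)
        mirrored = traj.frames.copy()
        it = arm.terminal_selection.indices
        mirrored[0, it, 2] *= -1.0  # plane is z = 0 by construction
        traj2 = core_io.Trajectory(traj.topology, mirrored)
        _, beta_down = compute_linker_angles(traj2, plane, arm)
        assert beta_down.values[0] == pytest.approx(-beta_up.values[0], abs=1e-9)

    def test_rigid_body_invariance(self, rng):
        traj, truth, plane = self._chromatosome(
            alpha_entry=25.0, alpha_exit=40.0, beta_entry=-15.0, beta_exit=20.0
        )
        arm = arm_spec_from_truth(traj.topology, truth, "exit")
        alpha0, beta0 = compute_linker_angles(traj, plane, arm)
        rot = Rotation.random(random_state=11).as_matrix()
        trans = rng.normal(size=3) * 50
        moved = core_io.Trajectory(traj.topology, traj.frames @ rot.T + trans)
        alpha1, beta1 = compute_linker_angles(moved, plane, arm)
        assert alpha1.values[0] == pytest.approx(alpha0.values[0], abs=1e-6)
        assert beta1.values[0] == pytest.approx(beta0.values[0], abs=1e-6)


class TestEndToEnd:
    def test_three_four_five(self):
        frames = np.array([[[0.0, 0, 0], [3.0, 4.0, 0]]])
        traj = make_trajectory(frames)
        d = end_to_end_distance(traj, sel(0), sel(1))
        assert d[0] == pytest.approx(5.0)

    def test_same_selection_zero(self):
        traj = make_trajectory(np.array([[[1.0, 2, 3], [4.0, 5, 6]]]))
        assert end_to_end_distance(traj, sel(0, 1), sel(0, 1))[0] == 0.0

    def test_random_matches_oracle(self, rng):
        frames = rng.normal(size=(4, 6, 3))
        traj = make_trajectory(frames)
        a, b = sel(0, 1, 2), sel(3, 4, 5)
        d = end_to_end_distance(traj, a, b)
        for f in range(4):
            expected = np.linalg.norm(
                frames[f, :3].mean(axis=0) - frames[f, 3:].mean(axis=0)
            )
            assert d[f] == pytest.approx(expected, abs=1e-9)

    def test_empty_selection_errors(self):
        traj = make_trajectory(np.zeros((1, 2, 3)))
        with pytest.raises(SelectionEmptyError):
            end_to_end_distance(traj, sel(), sel(0))


class TestContacts:
    def test_boundary_inside(self):
        frames = np.tile(np.array([[[0.0, 0, 0], [3.9, 0, 0]]]), (10, 1, 1))
        traj = make_trajectory(frames, resids=[1, 2])
        table = contact_table(traj, sel(0), sel(1), cutoff=4.0)
        assert table.pairs.iloc[0]["fraction"] == 1.0

    def test_boundary_outside(self):
        frames = np.tile(np.array([[[0.0, 0, 0], [4.1, 0, 0]]]), (10, 1, 1))
        traj = make_trajectory(frames, resids=[1, 2])
        table = contact_table(traj, sel(0), sel(1), cutoff=4.0)
        assert table.pairs.empty

    def test_hydrogens_excluded(self):
        frames = np.array([[[0.0, 0, 0], [1.0, 0, 0]]])
        traj = make_trajectory(frames, elements=["C", "H"], resids=[1, 2])
        with pytest.raises(SelectionEmptyError):
            contact_table(traj, sel(0), sel(1), cutoff=4.0)

    def test_matches_brute_force(self, rng):
        n = 50
        frames = rng.uniform(0, 15, size=(5, n, 3))
        resids = list(rng.integers(1, 10, size=n))
        traj = make_trajectory(frames, resids=resids)
        ia, ib = sel(*range(25)), sel(*range(25, 50))
        table = contact_table(traj, ia, ib, cutoff=4.0)
        got = {
            (row.residue_a, row.residue_b): row.frames_in_contact
            for row in table.pairs.itertuples()
        }
        expected: dict = {}
        for f in range(5):
            seen = set()
            for i in ia.indices:
                for j in ib.indices:
                    if np.linalg.norm(frames[f, i] - frames[f, j]) <= 4.0:
                        seen.add((resids[i], resids[j]))
            for pair in seen:
                expected[pair] = expected.get(pair, 0) + 1
        assert got == expected

    def test_bad_cutoff(self):
        traj = make_trajectory(np.zeros((1, 2, 3)), resids=[1, 2])
        with pytest.raises(ParameterError):
            contact_table(traj, sel(0), sel(1), cutoff=-1.0)

    def test_group_totals_shape(self, rng):
        frames = rng.uniform(0, 8, size=(4, 20, 3))
        resids = [i // 2 + 1 for i in range(20)]
        traj = make_trajectory(frames, resids=resids)
        table = contact_table(traj, sel(*range(10)), sel(*range(10, 20)), cutoff=4.0)
        totals = table.group_totals({"first": {1, 2}, "rest": {3, 4, 5}})
        assert set(totals.columns) == {"group", "mean_contacts", "sd_contacts"}
        assert (totals["sd_contacts"] >= 0).all()


class TestRmsd:
    def test_identical_is_zero(self, rng):
        coords = rng.normal(size=(8, 3))
        traj = make_trajectory(coords[None])
        ref = traj.topology
        assert rmsd(traj, sel(*range(8)), sel(*range(8)), ref)[0] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_rigid_rotation_is_zero_after_fit(self, rng):
        coords = rng.normal(size=(8, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        traj = make_trajectory((coords @ rot.T + [5, -2, 1])[None])
        ref = StructureFrame(traj.topology.atoms, coords)
        s = sel(*range(8))
        assert rmsd(traj, s, s, ref)[0] == pytest.approx(0.0, abs=1e-9)

    def test_known_offsets(self, rng):
        coords = rng.normal(size=(20, 3)) * 10
        offsets = np.zeros((20, 3))
        offsets[10:] = [[1.0, 0, 0]] * 10  # displace measure atoms only
        traj = make_trajectory((coords + offsets)[None])
        ref = StructureFrame(traj.topology.atoms, coords)
        fit = sel(*range(10))
        measure = sel(*range(10, 20))
        got = rmsd(traj, fit, measure, ref)[0]
        assert got == pytest.approx(1.0, abs=1e-9)

    def test_fitting_never_increases_rmsd(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            ref_coords = r.normal(size=(10, 3)) * 5
            frame = ref_coords + r.normal(size=(10, 3))
            traj = make_trajectory(frame[None])
            ref = StructureFrame(traj.topology.atoms, ref_coords)
            s = sel(*range(10))
            fitted = rmsd(traj, s, s, ref)[0]
            raw = np.sqrt(((frame - ref_coords) ** 2).sum(axis=1).mean())
            assert fitted <= raw + 1e-12

    def test_count_mismatch_errors(self, rng):
        traj = make_trajectory(rng.normal(size=(1, 6, 3)))
        ref = traj.topology
        with pytest.raises(StructuralMismatchError):
            rmsd(traj, sel(0, 1), sel(2), ref, ref_fit_sel=sel(0))
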