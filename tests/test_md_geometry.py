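"""Superposition, principal axes, MTBD/stalk angles, histogram fits, RMSF.

Rigid-rotation fixtures are exact oracles: rotating the mobile chain by a
known matrix must reproduce the programmed angle to machine precision.
"""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from motorforge.md_geometry import (
    GeometryError,
    angle_histogram_fit,
    mtbd_angle,
    mtbd_angle_series,
    principal_axes,
    rmsf,
    rmsf_percent_change,
    stalk_angle,
    stalk_angle_series,
    superpose,
)
from motorforge.structures import StructureFrame, Trajectory
from motorforge.synthetic_data import (
    SyntheticTrajectoryParams,
    make_reference_structure,
    simulate_mtbd_trajectory,
)

DYN = "D"
TUB = "A"


def _rotate_chain(frame, chain, rot):
    out = frame.copy()
    mask = out.chain_id == chain
    out.coord[mask] = rot.apply(out.coord[mask])
    return out


def _rotate_all(frame, rot):
    return frame.with_coord(rot.apply(frame.coord))


class TestSuperpose:
    def test_identical_structures_give_identity(self, reference_structure):
        tf = superpose(reference_structure.coord, reference_structure.coord)
        assert tf.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-12)

    def test_known_rotation_recovered(self, reference_structure):
        rot = Rotation.from_euler("xyz", [25.0, 0.0, 0.0], degrees=True)
        moved = rot.apply(reference_structure.coord)
        tf = superpose(moved, reference_structure.coord)
        recovered = Rotation.from_matrix(tf.rotation)
        angle = math.degrees(recovered.magnitude())
        assert angle == pytest.approx(25.0, abs=1e-6)
        assert tf.rmsd == pytest.approx(0.0, abs=1e-8)

    def test_reflection_still_yields_proper_rotation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        tf = superpose(mirrored, pts)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        assert tf.rmsd > 0.1

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError):
            superpose(line, line)

    def test_matches_reference_library_implementation(
            self, reference_structure):
        import biotite.structure as struc
        from motorforge.structures import to_biotite
        rng = np.random.default_rng(2)
        rot = Rotation.random(random_state=3)
        moved = reference_structure.with_coord(
            rot.apply(reference_structure.coord) + rng.normal(0, 0.3,
            reference_structure.coord.shape))
        tf = superpose(moved.coord, reference_structure.coord)
        fitted, transform = struc.superimpose(
            to_biotite(reference_structure), to_biotite(moved))
        assert np.allclose(tf.apply(moved.coord), fitted.coord, atol=1e-3)


class TestPrincipalAxes:
    def test_synthetic_rod_gives_canonical_frame(self, reference_structure):
        axes = principal_axes(reference_structure)
        assert np.allclose(axes.pa1, [0, 0, 1], atol=1e-12)
        assert np.allclose(axes.pa2, [1, 0, 0], atol=1e-12)
        assert np.allclose(axes.pa3, [0, 1, 0], atol=1e-12)

    def test_axes_are_orthonormal(self, reference_structure):
        axes = principal_axes(reference_structure)
        m = np.vstack([axes.pa1, axes.pa2, axes.pa3])
        assert np.allclose(m @ m.T, np.eye(3), atol=1e-12)
        # right-handed
        assert np.dot(np.cross(axes.pa1, axes.pa2), axes.pa3) == \
            pytest.approx(1.0)

    def test_equivariance_under_global_rotation(self, reference_structure):
        rot = Rotation.from_euler("zyx", [31.0, -12.0, 7.0], degrees=True)
        rotated = _rotate_all(reference_structure, rot)
        axes = principal_axes(reference_structure)
        axes_rot = principal_axes(rotated, reference_pa1=rot.apply(axes.pa1))
        for a, b in [(axes.pa1, axes_rot.pa1), (axes.pa2, axes_rot.pa2),
                     (axes.pa3, axes_rot.pa3)]:
            assert np.allclose(rot.apply(a), b, atol=1e-9)

    def test_near_spherical_cloud_rejected(self):
        rng = np.random.default_rng(4)
        n = 500
        coord = rng.normal(size=(n, 3))  # isotropic: no long axis
        frame = StructureFrame(
            chain_id=np.full(n, TUB), res_id=np.arange(n) + 1,
            res_name=np.full(n, "ALA"), atom_name=np.full(n, "CA"),
            element=np.full(n, "C"), coord=coord * 10)
        with pytest.raises(GeometryError):
            principal_axes(frame, anchor_chain=TUB, anchor_res_ids=(1, 2))


class TestAngles:
    @pytest.mark.parametrize("angle", [10.0, -7.9, 11.5, 179.0, -90.0])
    def test_rigid_rotation_about_pa1_measured_exactly(
            self, reference_structure, angle):
        axes = principal_axes(reference_structure)
        rot = Rotation.from_rotvec(np.radians(angle) * np.array([0, 0, 1.0]))
        frame = _rotate_chain(reference_structure, DYN, rot)
        assert mtbd_angle(frame, axes) == pytest.approx(angle, abs=1e-6)

    def test_unrotated_reference_is_zero(self, reference_structure):
        axes = principal_axes(reference_structure)
        assert mtbd_angle(reference_structure, axes) == pytest.approx(
            0.0, abs=1e-9)

    def test_reference_zero_subtraction(self, reference_structure):
        axes = principal_axes(reference_structure)
        rot = Rotation.from_rotvec(np.radians(4.0) * np.array([0, 0, 1.0]))
        frame = _rotate_chain(reference_structure, DYN, rot)
        assert mtbd_angle(frame, axes, reference_zero=4.0) == pytest.approx(
            0.0, abs=1e-9)

    def test_pa1pa2_projection_plane_reads_out_of_plane_tilt(
            self, reference_structure):
        axes = principal_axes(reference_structure)
        # tilt the MTBD vector toward -PA1 (about the PA3 = y axis)
        rot = Rotation.from_rotvec(np.radians(15.0) * np.array([0, 1.0, 0]))
        frame = _rotate_chain(reference_structure, DYN, rot)
        a12 = mtbd_angle(frame, axes, plane="PA1PA2")
        assert a12 == pytest.approx(15.0, abs=1e-6)
        # the perpendicular-plane angle is unaffected by this tilt
        assert mtbd_angle(frame, axes, plane="PA2PA3") == pytest.approx(
            0.0, abs=1e-9)

    def test_angle_series_equivariant_under_global_rotation(self):
        traj = simulate_mtbd_trajectory(SyntheticTrajectoryParams(
            angle_components=((0.5, 8.0, 2.0), (0.5, -5.0, 2.0)),
            n_frames=50, seed=5))
        ref = traj.reference
        series = mtbd_angle_series(traj.frames, ref)
        rot = Rotation.from_euler("xyz", [15.0, 75.0, -40.0], degrees=True)
        ref_rot = _rotate_all(ref, rot)
        traj_rot = Trajectory(topology=ref_rot,
                              coords=rot.apply(
                                  traj.frames.coords.reshape(-1, 3)
                              ).reshape(traj.frames.coords.shape))
        series_rot = mtbd_angle_series(traj_rot, ref_rot)
        assert np.allclose(series, series_rot, atol=1e-7)


class TestStalkAngle:
    @pytest.mark.parametrize("programmed", [60.0, 0.0, 90.0, 46.3])
    def test_constructed_stalk_angles(self, programmed):
        ref = make_reference_structure(stalk_angle_deg=programmed)
        axes = principal_axes(ref)
        assert stalk_angle(ref, axes, ref) == pytest.approx(programmed,
                                                            abs=1e-6)

    def test_series_on_rotated_frames(self):
        ref = make_reference_structure(stalk_angle_deg=59.9)
        traj = simulate_mtbd_trajectory(SyntheticTrajectoryParams(
            reference=ref, n_frames=5, seed=6))
        series = stalk_angle_series(traj.frames, ref, ref)
        # rotation about PA1 preserves the angle to PA1
        assert np.allclose(series, 59.9, atol=1e-6)


class TestAngleHistogramFit:
    def test_single_gaussian_recovery(self):
        rng = np.random.default_rng(7)
        fit = angle_histogram_fit(rng.normal(0.0, 5.0, 5000), 1)
        mu, sd = fit.peaks[0]
        assert mu == pytest.approx(0.0, abs=0.3)
        assert sd == pytest.approx(5.0, abs=0.3)

    def test_double_gaussian_recovery_within_half_degree(self):
        rng = np.random.default_rng(8)
        comp = rng.random(5000) < 0.5
        angles = np.where(comp, rng.normal(11.5, 4.0, 5000),
                          rng.normal(-7.9, 4.0, 5000))
        fit = angle_histogram_fit(angles, 2)
        assert fit.peaks[0][0] == pytest.approx(-7.9, abs=0.5)
        assert fit.peaks[1][0] == pytest.approx(11.5, abs=0.5)
        assert fit.peaks[0][1] == pytest.approx(4.0, rel=0.10)
        assert fit.peaks[1][1] == pytest.approx(4.0, rel=0.10)

    def test_histogram_mass_is_normalized(self):
        rng = np.random.default_rng(9)
        angles = rng.normal(3.0, 2.0, 1000)
        lo = math.floor(angles.min())
        hi = math.ceil(angles.max())
        counts, _ = np.histogram(angles, bins=np.arange(lo, hi + 0.5, 1.0))
        assert (counts / counts.sum()).sum() == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(GeometryError):
            angle_histogram_fit(np.zeros(50), 1)

    def test_mode_collapse_reported(self):
        rng = np.random.default_rng(10)
        with pytest.raises(GeometryError):
            angle_histogram_fit(rng.normal(0.0, 1.0, 5000), 2)


def _brute_force_rmsf(coords, res_ids):
    """Independent per-atom RMSF: plain loops, no vectorization."""
    n_frames, n_atoms, _ = coords.shape
    out = {}
    for a in range(n_atoms):
        mean = [sum(coords[f, a, k] for f in range(n_frames)) / n_frames
                for k in range(3)]
        acc = 0.0
        for f in range(n_frames):
            acc += sum((coords[f, a, k] - mean[k]) ** 2 for k in range(3))
        out.setdefault(res_ids[a], []).append(math.sqrt(acc / n_frames))
    return {rid: sum(v) / len(v) for rid, v in out.items()}


class TestRMSF:
    def _masks(self, ref):
        return ref.chain_id == TUB, (ref.chain_id == DYN) \
            & (ref.atom_name == "CA")

    def test_static_trajectory_has_zero_rmsf(self, reference_structure):
        ref = reference_structure
        traj = simulate_mtbd_trajectory(SyntheticTrajectoryParams(n_frames=5))
        align, report = self._masks(ref)
        prof = rmsf(traj.frames, ref, align, report)
        assert np.allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_isotropic_noise_rmsf_is_sqrt3_sigma(self, reference_structure):
        sigma = 0.5
        traj = simulate_mtbd_trajectory(SyntheticTrajectoryParams(
            positional_noise_sd=sigma, n_frames=10000, seed=11))
        align, report = self._masks(reference_structure)
        prof = rmsf(traj.frames, reference_structure, align, report)
        assert np.mean(prof.rmsf) == pytest.approx(math.sqrt(3) * sigma,
                                                   rel=0.02)

    def test_matches_brute_force_oracle(self, reference_structure):
        traj = simulate_mtbd_trajectory(SyntheticTrajectoryParams(
            positional_noise_sd=0.8, n_frames=20, seed=12))
        align, report = self._masks(reference_structure)
        prof = rmsf(traj.frames, reference_structure, align, report)
        # noise is mobile-only, so tubulin alignment is the identity and the
        # brute-force per-atom computation must agree exactly
        brute = _brute_force_rmsf(traj.frames.coords[:, report, :],
                                  list(reference_structure.res_id[report]))
        for rid, val in zip(prof.res_ids, prof.rmsf):
            assert val == pytest.approx(brute[rid], abs=1e-9)

    def test_percent_change_arithmetic(self, reference_structure):
        traj = simulate_mtbd_trajectory(SyntheticTrajectoryParams(
            positional_noise_sd=0.5, n_frames=200, seed=13))
        align, report = self._masks(reference_structure)
        a = rmsf(traj.frames, reference_structure, align, report)
        from motorforge.md_geometry import RMSFProfile
        b = RMSFProfile(res_ids=a.res_ids, rmsf=1.169 * a.rmsf)
        assert rmsf_percent_change(a, b) == pytest.approx(16.9, abs=1e-9)

    def test_residue_range_restriction(self, reference_structure):
        traj = simulate_mtbd_trajectory(SyntheticTrajectoryParams(
            positional_noise_sd=0.5, n_frames=100, seed=14))
        align, report = self._masks(reference_structure)
        a = rmsf(traj.frames, reference_structure, align, report)
        from motorforge.md_geometry import RMSFProfile
        scaled = a.rmsf.copy()
        sel = (a.res_ids >= 3300) & (a.res_ids <= 3340)
        scaled[sel] *= 1.257
        b = RMSFProfile(res_ids=a.res_ids, rmsf=scaled)
        assert rmsf_percent_change(a, b, res_range=(3300, 3340)) == \
            pytest.approx(25.7, abs=1e-9)

    def test_single_frame_rejected(self, reference_structure):
        traj = simulate_mtbd_trajectory(SyntheticTrajectoryParams(n_frames=1))
        align, report = self._masks(reference_structure)
        with pytest.raises(GeometryError):
            rmsf(traj.frames, reference_structure, align, report)

    def test_rmsf_equivariant_under_global_rotation(self, reference_structure):
        traj = simulate_mtbd_trajectory(SyntheticTrajectoryParams(
            positional_noise_sd=0.5, n_frames=100, seed=15))
        ref = reference_structure
        align, report = self._masks(ref)
        prof = rmsf(traj.frames, ref, align, report)
        rot = Rotation.from_euler("xyz", [45.0, -30.0, 60.0], degrees=True)
        ref_rot = _rotate_all(ref, rot)
        coords_rot = rot.apply(traj.frames.coords.reshape(-1, 3)).reshape(
            traj.frames.coords.shape)
        prof_rot = rmsf(Trajectory(topology=ref_rot, coords=coords_rot),
                        ref_rot, align, report)
        assert np.allclose(prof.rmsf, prof_rot.rmsf, atol=1e-9)
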