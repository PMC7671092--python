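"""Joint primitives, joint-model fitting and disparate-frame selection."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from skullkin.core import FitPointSet, Pose
from skullkin.joints import (JointModel, JointType, Strut, fit_joint_model,
                             joint_transform, select_disparate_frames,
                             select_joint_model)

FIT_PTS = FitPointSet("child", np.array([[8.0, 1.0, 0.5],
                                         [2.0, 6.0, -1.0],
                                         [-3.0, 2.0, 7.0]]))


def revolute_pose(center, axis, angle):
    R = Rotation.from_rotvec(np.asarray(axis) / np.linalg.norm(axis)
                             * angle).as_matrix()
    c = np.asarray(center, float)
    return Pose(R, c - R @ c)


class TestJointType:
    def test_dof_mapping(self):
        assert [JointType.REVOLUTE.dof, JointType.UNIVERSAL.dof,
                JointType.SPHERICAL.dof, JointType.PRISMATIC.dof] \
            == [1, 2, 3, 1]


class TestJointTransform:
    def test_zero_coords_identity(self):
        for jt, axes in ((JointType.REVOLUTE, [[0, 0, 1]]),
                         (JointType.UNIVERSAL, [[1, 0, 0], [0, 1, 0]]),
                         (JointType.SPHERICAL, np.eye(3)),
                         (JointType.PRISMATIC, [[1, 0, 0]])):
            m = JointModel(jt, [3.0, -2.0, 1.0], axes)
            p = joint_transform(m, np.zeros(jt.dof))
            assert np.allclose(p.rotation, np.eye(3), atol=1e-12)
            assert np.allclose(p.translation, 0, atol=1e-12)

    def test_revolute_quarter_turn_about_z(self):
        m = JointModel(JointType.REVOLUTE, np.zeros(3), [[0, 0, 1]])
        p = joint_transform(m, [np.pi / 2])
        assert np.allclose(p.rotation,
                           [[0, -1, 0], [1, 0, 0], [0, 0, 1]], atol=1e-12)

    def test_spherical_equals_sequential_revolutes(self):
        # compose three single-axis rotations by hand and compare
        rng = np.random.default_rng(0)
        axes, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        axes = axes.T
        center = rng.uniform(-5, 5, 3)
        q = rng.uniform(-1, 1, 3)
        sph = joint_transform(JointModel(JointType.SPHERICAL, center, axes), q)
        seq = Pose.identity()
        for a, ang in zip(axes, q):
            seq = seq @ revolute_pose(center, a, ang)
        assert np.allclose(sph.rotation, seq.rotation, atol=1e-12)
        assert np.allclose(sph.translation, seq.translation, atol=1e-12)

    def test_wrong_coordinate_count(self):
        m = JointModel(JointType.REVOLUTE, np.zeros(3), [[0, 0, 1]])
        with pytest.raises(ValueError):
            joint_transform(m, [0.1, 0.2])


class TestJointModelValidation:
    def test_universal_needs_independent_axes(self):
        with pytest.raises(ValueError):
            JointModel(JointType.UNIVERSAL, np.zeros(3),
                       [[1, 0, 0], [1, 0, 0]])

    def test_axes_normalized(self):
        m = JointModel(JointType.REVOLUTE, np.zeros(3), [[0, 0, 2.0]])
        assert np.allclose(np.linalg.norm(m.axes, axis=1), 1.0)


class TestStrut:
    def test_rest_length_and_axis(self):
        s = Strut("lig", "a", [0, 0, 0], "b", [3.0, 4.0, 0.0])
        assert s.rest_length == pytest.approx(5.0)
        assert np.allclose(s.axis, [0.6, 0.8, 0.0])

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            Strut("lig", "a", [1, 1, 1], "b", [1, 1, 1])


class TestFitJointModel:
    axis = np.array([0.3, -0.5, 0.81])
    center = np.array([4.0, -2.0, 1.5])

    def _revolute_poses(self, angles):
        return [revolute_pose(self.center, self.axis, a) for a in angles]

    def test_noise_free_revolute_recovered(self):
        poses = self._revolute_poses(np.linspace(-0.6, 0.9, 12))
        fit = fit_joint_model(poses, JointType.REVOLUTE, FIT_PTS, seed=0)
        assert fit.fit_rms < 1e-6
        u = self.axis / np.linalg.norm(self.axis)
        cosang = abs(float(fit.axes[0] @ u))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 0.1

    def test_spherical_motion_fitted_as_revolute_has_large_error(self):
        rng = np.random.default_rng(1)
        poses = []
        for _ in range(15):
            R = Rotation.from_euler(
                "xyz", rng.uniform(-0.5, 0.5, 3)).as_matrix()
            poses.append(Pose(R, self.center - R @ self.center))
        rev = fit_joint_model(poses, JointType.REVOLUTE, FIT_PTS, seed=0)
        sph = fit_joint_model(poses, JointType.SPHERICAL, FIT_PTS, seed=0)
        assert sph.fit_rms < 1e-6
        # mismatch is far beyond tracking precision (0.08 mm), so the
        # lower-DoF model is detectably wrong and would never be selected
        assert rev.fit_rms > 10 * 0.08

    def test_noisy_revolute_rms_matches_monte_carlo_scale(self):
        rng = np.random.default_rng(2)
        sigma = 0.05
        angles = np.linspace(-0.6, 0.9, 12)
        # oracle: distribution of fit RMS when the true geometry is known
        oracle = []
        for _ in range(30):
            resid = rng.normal(0, sigma, size=(len(angles), 3, 3))
            oracle.append(np.sqrt(np.mean(np.sum(resid ** 2, axis=2))))
        lo, hi = np.quantile(oracle, [0.0, 1.0])
        noisy = []
        for a in angles:
            p = revolute_pose(self.center, self.axis, a)
            pts = p.apply(FIT_PTS.points) + rng.normal(0, sigma, (3, 3))
            noisy.append(pts)
        # fit against noisy targets by rebuilding poses through alignment
        from skullkin.core import solve_rigid_alignment
        poses = [solve_rigid_alignment(FIT_PTS.points, pts)[0]
                 for pts in noisy]
        fit = fit_joint_model(poses, JointType.REVOLUTE, FIT_PTS, seed=0)
        assert 0.2 * lo < fit.fit_rms < 1.5 * hi
        assert fit.fit_rms == pytest.approx(sigma * np.sqrt(3), rel=0.6)

    def test_nested_models_error_never_increases_with_dof(self):
        rng = np.random.default_rng(3)
        poses = []
        for _ in range(14):
            R = Rotation.from_euler(
                "xy", rng.uniform(-0.4, 0.4, 2)).as_matrix()
            t = self.center - R @ self.center + rng.normal(0, 0.02, 3)
            poses.append(Pose(R, t))
        fits = {jt: fit_joint_model(poses, jt, FIT_PTS, seed=0)
                for jt in (JointType.REVOLUTE, JointType.UNIVERSAL,
                           JointType.SPHERICAL)}
        tol = 1e-8
        assert fits[JointType.UNIVERSAL].fit_rms \
            <= fits[JointType.REVOLUTE].fit_rms + tol
        assert fits[JointType.SPHERICAL].fit_rms \
            <= fits[JointType.UNIVERSAL].fit_rms + tol

    def test_fitted_model_reproduces_inputs_at_fitted_coordinates(self):
        poses = self._revolute_poses(np.linspace(-0.5, 0.5, 8))
        fit = fit_joint_model(poses, JointType.REVOLUTE, FIT_PTS, seed=0)
        errs = []
        for t, p in enumerate(poses):
            model = joint_transform(fit, fit.coordinates[t])
            errs.append(np.linalg.norm(
                model.apply(FIT_PTS.points) - p.apply(FIT_PTS.points),
                axis=1))
        rms = np.sqrt(np.mean(np.square(errs)))
        assert rms == pytest.approx(fit.fit_rms, abs=1e-9)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            fit_joint_model(self._revolute_poses([0.1]),
                            JointType.REVOLUTE, FIT_PTS)


class TestSelectJointModel:
    def _fits(self, r, u, s):
        out = {}
        for jt, rms in ((JointType.REVOLUTE, r), (JointType.UNIVERSAL, u),
                        (JointType.SPHERICAL, s)):
            m = JointModel(jt, np.zeros(3), np.eye(3)[:jt.n_axes])
            m.fit_rms = rms
            out[jt] = m
        return out

    def test_hinge_data_selects_revolute(self):
        poses = [revolute_pose([1.0, 2, 0], [0, 0, 1], a)
                 for a in np.linspace(-0.5, 0.8, 10)]
        fits = {jt: fit_joint_model(poses, jt, FIT_PTS, seed=0)
                for jt in (JointType.REVOLUTE, JointType.UNIVERSAL,
                           JointType.SPHERICAL)}
        assert select_joint_model(fits, precision=0.08).type \
            is JointType.REVOLUTE

    def test_ball_data_selects_spherical(self):
        rng = np.random.default_rng(4)
        poses = []
        c = np.array([1.0, 2.0, 0.0])
        for _ in range(15):
            R = Rotation.from_euler("xyz",
                                    rng.uniform(-0.5, 0.5, 3)).as_matrix()
            poses.append(Pose(R, c - R @ c))
        fits = {jt: fit_joint_model(poses, jt, FIT_PTS, seed=0)
                for jt in (JointType.REVOLUTE, JointType.UNIVERSAL,
                           JointType.SPHERICAL)}
        assert select_joint_model(fits, precision=0.08).type \
            is JointType.SPHERICAL

    def test_equal_errors_tie_breaks_to_lowest_dof(self):
        chosen = select_joint_model(self._fits(0.1, 0.1, 0.1),
                                    precision=0.08)
        assert chosen.type is JointType.REVOLUTE
        assert "selection" in chosen.meta

    def test_missing_candidate_rejected(self):
        fits = self._fits(0.1, 0.1, 0.1)
        del fits[JointType.UNIVERSAL]
        with pytest.raises(ValueError):
            select_joint_model(fits, precision=0.08)


class TestSelectDisparateFrames:
    def test_all_frames_sorted_ascending(self):
        data = np.random.default_rng(5).normal(size=(6, 4))
        sel = select_disparate_frames(data, 6)
        assert np.array_equal(sel, np.arange(6))

    def test_ramp_endpoints_maximize_spread(self):
        # brute force over all pairs confirms {0, n-1} is the max-spread pair
        x = np.linspace(0.0, 1.0, 11)[:, None]
        best = max(((i, j) for i in range(11) for j in range(i + 1, 11)),
                   key=lambda ij: abs(x[ij[0], 0] - x[ij[1], 0]))
        sel = select_disparate_frames(x, 2)
        assert set(sel) == set(best) == {0, 10}

    def test_duplicates_deferred_until_distinct_poses_exhausted(self):
        frames = np.array([[0.0], [1.0], [0.0], [2.0], [1.0], [3.0]])
        for k in range(2, 5):
            sel = select_disparate_frames(frames, k)
            assert len(np.unique(frames[sel])) == k
        sel5 = select_disparate_frames(frames, 5)
        assert len(np.unique(frames[sel5])) == 4   # now forced to repeat

    def test_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(20, 3, 3))
        sel = select_disparate_frames(data, 7)
        perm = rng.permutation(20)
        sel_p = select_disparate_frames(data[perm], 7)
        assert set(perm[sel_p]) == set(sel)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            select_disparate_frames(np.zeros((3, 2)), 4)
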