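"""Rigid-body math, alignment, smoothing and motion-capture benchmarks."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from skullkin.core import (DegenerateConfigurationError, MarkerTrajectory,
                           FitPointSet, Pose, precision_metric,
                           procrustes_consensus, rms_point_error,
                           smooth_trajectories, solve_rigid_alignment)


def random_pose(rng, scale=10.0):
    return Pose(Rotation.random(random_state=rng).as_matrix(),
                rng.uniform(-scale, scale, 3))


class TestPose:
    def test_identity_compose_inverse_closed(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p, q = random_pose(rng), random_pose(rng)
            (p @ q).validate(1e-9)
            p.inverse().validate(1e-9)
            r = p @ p.inverse()
            assert np.allclose(r.rotation, np.eye(3), atol=1e-12)
            assert np.allclose(r.translation, 0, atol=1e-12)

    def test_apply_matches_matrix_form(self):
        rng = np.random.default_rng(1)
        p = random_pose(rng)
        x = rng.normal(size=(5, 3))
        hom = np.c_[x, np.ones(5)] @ p.as_matrix().T
        assert np.allclose(p.apply(x), hom[:, :3])

    def test_reflection_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            Pose(R, np.zeros(3)).validate()


class TestRigidAlignment:
    def test_identical_points_give_identity(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [3, 2, 1]])
        pose, resid = solve_rigid_alignment(pts, pts)
        assert np.allclose(pose.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(pose.translation, 0, atol=1e-12)
        assert resid == pytest.approx(0, abs=1e-12)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.uniform(-10, 10, size=(6, 3))
            truth = random_pose(rng)
            pose, resid = solve_rigid_alignment(a, truth.apply(a))
            assert np.allclose(pose.rotation, truth.rotation, atol=1e-9)
            assert np.allclose(pose.translation, truth.translation, atol=1e-9)
            assert resid < 1e-9

    def test_noise_residual_matches_monte_carlo_oracle(self):
        # with iid noise sigma the aligned RMS residual concentrates around
        # a value the brute-force simulation below estimates independently
        rng = np.random.default_rng(3)
        n, sigma, reps = 6, 0.1, 1000
        a = rng.uniform(-10, 10, size=(n, 3))
        oracle = []
        for _ in range(reps):
            b = a + rng.normal(0, sigma, size=a.shape)
            oracle.append(solve_rigid_alignment(a, b)[1])
        oracle_mean = np.mean(oracle)
        test = np.mean([solve_rigid_alignment(
            a, a + rng.normal(0, sigma, size=a.shape))[1]
            for _ in range(200)])
        assert test == pytest.approx(oracle_mean, rel=0.05)
        # scale sanity: sqrt(3)*sigma*sqrt((n-?)/n) territory, not 0 or sigma*3
        assert 0.5 * sigma < oracle_mean < 2.0 * sigma

    def test_residual_invariant_under_common_rigid_transform(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-5, 5, size=(5, 3))
        b = a + rng.normal(0, 0.2, size=a.shape)
        _, r0 = solve_rigid_alignment(a, b)
        for _ in range(10):
            g = random_pose(rng)
            _, r1 = solve_rigid_alignment(g.apply(a), g.apply(b))
            assert r1 == pytest.approx(r0, abs=1e-9)

    @pytest.mark.parametrize("bad", [
        np.array([[0.0, 0, 0], [1, 0, 0]]),                      # n < 3
        np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]),           # collinear
    ])
    def test_degenerate_configurations_rejected(self, bad):
        with pytest.raises(DegenerateConfigurationError):
            solve_rigid_alignment(bad, bad)


class TestRmsPointError:
    def test_closed_forms(self):
        a = np.zeros((3, 3))
        assert rms_point_error(a, a) == 0.0
        b = a.copy()
        b[0, 0] = 3.0
        assert rms_point_error(a, b) == pytest.approx(np.sqrt(3.0))

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=(7, 3))
            b = rng.normal(size=(7, 3))
            brute = np.sqrt(sum(np.sum((pa - pb) ** 2)
                                for pa, pb in zip(a, b)) / 7)
            assert rms_point_error(a, b) == pytest.approx(brute, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            rms_point_error(np.zeros((3, 3)), np.zeros((4, 3)))


class TestSmoothing:
    fs = 300.0

    def _traj(self, x):
        pos = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
        return MarkerTrajectory("m", "b", pos, self.fs)

    def test_constant_unchanged(self):
        tr = self._traj(np.full(400, 3.2))
        sm = smooth_trajectories(tr, cutoff=25.0)
        assert np.allclose(sm.positions[:, 0], 3.2, atol=1e-9)

    def test_passband_sinusoid_amplitude_preserved(self):
        t = np.arange(1500) / self.fs
        tr = self._traj(np.sin(2 * np.pi * 5.0 * t))
        sm = smooth_trajectories(tr, cutoff=25.0)
        mid = slice(300, 1200)   # avoid edge transients
        amp = np.ptp(sm.positions[mid, 0]) / 2
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_stopband_noise_power_reduced(self):
        t = np.arange(1500) / self.fs
        sig = np.sin(2 * np.pi * 5.0 * t)
        noise = 0.5 * np.sin(2 * np.pi * 100.0 * t)
        sm = smooth_trajectories(self._traj(sig + noise), cutoff=25.0)
        resid = sm.positions[300:1200, 0] - sig[300:1200]
        assert np.mean(noise[300:1200] ** 2) / np.mean(resid ** 2) >= 100

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            smooth_trajectories(self._traj(np.zeros(100)), cutoff=150.0)

    def test_missing_frames_interpolated_then_remasked(self):
        x = np.linspace(0.0, 10.0, 300)
        pos = np.column_stack([x, x, x])
        pos[50:55] = np.nan
        tr = MarkerTrajectory("m", "b", pos, self.fs)
        sm = smooth_trajectories(tr, cutoff=25.0)
        assert np.isnan(sm.positions[52, 0])
        assert sm.missing[52]
        good = ~sm.missing
        assert np.allclose(sm.positions[good, 0], x[good], atol=0.05)


class TestPrecisionMetric:
    def _markers(self, rng, sigma, n_frames=120, n_markers=4):
        base = rng.uniform(-10, 10, size=(n_markers, 3))
        out = []
        for k in range(n_markers):
            world = []
            for f in range(n_frames):
                ang = 0.01 * f
                R = Rotation.from_euler("xyz", [ang, ang / 2, 0]).as_matrix()
                world.append(R @ base[k] + np.array([0.1 * f, 0, 0])
                             + rng.normal(0, sigma, 3))
            out.append(MarkerTrajectory(f"m{k}", "b", np.array(world), 300.0))
        return {"b": out}

    def test_noise_free_rigid_motion_is_zero(self):
        rng = np.random.default_rng(7)
        pm = precision_metric(self._markers(rng, 0.0), n_frames=50, seed=0)
        assert pm["b"] == pytest.approx(0.0, abs=1e-9)

    def test_noise_scale_matches_monte_carlo_oracle(self):
        # oracle: direct simulation of the same align-to-consensus
        # computation on pure noise, 500 replicates
        rng = np.random.default_rng(8)
        sigma, n_markers = 0.08, 4
        base = rng.uniform(-10, 10, size=(n_markers, 3))
        oracle = []
        for _ in range(500):
            shapes = [base + rng.normal(0, sigma, base.shape)
                      for _ in range(10)]
            _, devs = procrustes_consensus(shapes)
            oracle.append(np.sqrt(np.mean(devs ** 2)))
        expected = float(np.mean(oracle))
        pm = precision_metric(self._markers(rng, sigma), n_frames=50, seed=1)
        assert pm["b"] == pytest.approx(expected, rel=0.15)
        assert 0.5 * sigma < pm["b"] < 1.6 * sigma

    def test_single_frame_distance_to_itself_is_zero(self):
        rng = np.random.default_rng(9)
        markers = self._markers(rng, 0.05, n_frames=40)
        pm = precision_metric(markers, n_frames=1, seed=2)
        assert pm["b"] == pytest.approx(0.0, abs=1e-9)

    def test_seed_irrelevant_when_all_frames_used(self):
        rng = np.random.default_rng(10)
        markers = self._markers(rng, 0.05, n_frames=30)
        a = precision_metric(markers, n_frames=30, seed=1)["b"]
        b = precision_metric(markers, n_frames=30, seed=99)["b"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_too_few_markers_warns_and_returns_nan(self):
        rng = np.random.default_rng(11)
        markers = self._markers(rng, 0.05)
        markers["b"] = markers["b"][:2]
        with pytest.warns(UserWarning):
            pm = precision_metric(markers, n_frames=10, seed=0)
        assert np.isnan(pm["b"])


class TestProcrustes:
    def test_identical_shapes_zero_deviation(self):
        s = np.array([[0.0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 3]])
        _, devs = procrustes_consensus([s, s.copy()])
        assert np.allclose(devs, 0, atol=1e-12)

    def test_rotated_copies_zero_deviation(self):
        rng = np.random.default_rng(12)
        s = rng.uniform(-5, 5, size=(5, 3))
        shapes = [random_pose(rng).apply(s) for _ in range(3)]
        _, devs = procrustes_consensus(shapes)
        assert np.allclose(devs, 0, atol=1e-9)

    def test_symmetric_perturbation_closed_form(self):
        # two shapes = consensus +- d on one landmark's z.  To first order
        # the superimposition removes the component of the perturbation that
        # a rigid motion of the whole shape can mimic, so each shape's RMS
        # deviation equals |P_perp(delta)|/sqrt(k), with P_perp the
        # projection off the 6-dim rigid-motion tangent space (translations
        # and infinitesimal rotations about the centroid) - computed here as
        # an independent linear-algebra oracle.
        s = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]])
        d = 0.01   # small so the first-order analysis is exact
        k = s.shape[0]
        delta = np.zeros((k, 3))
        delta[0, 2] = d
        c = s - s.mean(axis=0)
        basis = []
        for j in range(3):
            t = np.zeros((k, 3))
            t[:, j] = 1.0
            basis.append(t.ravel())
            w = np.zeros(3)
            w[j] = 1.0
            basis.append(np.cross(np.broadcast_to(w, c.shape), c).ravel())
        B = np.array(basis).T
        resid = delta.ravel() - B @ np.linalg.lstsq(B, delta.ravel(),
                                                    rcond=None)[0]
        expected = np.linalg.norm(resid) / np.sqrt(k)
        up, dn = s.copy(), s.copy()
        up[0, 2] += d
        dn[0, 2] -= d
        _, devs = procrustes_consensus([up, dn])
        assert np.allclose(devs, expected, rtol=0.01)
        assert expected > 0.5 * d / np.sqrt(k)   # perturbation not absorbed

    def test_deviations_invariant_to_rigid_pretransforms(self):
        rng = np.random.default_rng(13)
        base = rng.uniform(-5, 5, size=(6, 3))
        shapes = [base + rng.normal(0, 0.3, base.shape) for _ in range(4)]
        _, devs0 = procrustes_consensus(shapes)
        moved = [random_pose(rng).apply(s) for s in shapes]
        _, devs1 = procrustes_consensus(moved)
        assert np.allclose(np.sort(devs0), np.sort(devs1), atol=1e-8)

    def test_inconsistent_landmark_counts(self):
        with pytest.raises(ValueError):
            procrustes_consensus([np.zeros((4, 3)), np.zeros((5, 3))])


def test_fit_point_set_requires_three_noncollinear():
    with pytest.raises(ValueError):
        FitPointSet("b", np.zeros((4, 3)))
    with pytest.raises(DegenerateConfigurationError):
        FitPointSet("b", [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
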