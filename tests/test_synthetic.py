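"""The synthetic-data generator: wave trains, simulated recordings,
individuals, and end-to-end recovery round trips."""
import numpy as np
import pytest

from skullkin.core import precision_metric
from skullkin.fitting import fit_mechanism_frame, targets_from_poses
from skullkin.fixture import build_catfish_fixture
from skullkin.mechanism import forward_kinematics
from skullkin.synthetic import (WaveSpec, default_wave_spec,
                                generate_wave_trajectories, make_individual,
                                simulate_recording)


class TestWaveSpec:
    def test_rostrocaudal_requires_increasing_peaks(self):
        with pytest.raises(ValueError):
            WaveSpec("rostrocaudal",
                     amplitudes={"I": 0.3, "J": 0.1},
                     peak_offsets={"I": 0.05, "J": 0.0})

    def test_compressive_requires_hyoid_elevation_before_flaring(self):
        with pytest.raises(ValueError):
            WaveSpec("compressive",
                     amplitudes={"K": 0.1, "H": 0.1},   # K must be negative
                     peak_offsets={"K": -0.05, "H": 0.0})

    def test_default_templates_valid(self):
        for klass in ("rostrocaudal", "caudorostral", "compressive",
                      "slow_open"):
            spec = default_wave_spec(klass)
            assert spec.klass == klass


class TestGenerateWaveTrajectories:
    def test_rostrocaudal_peak_order(self):
        train = generate_wave_trajectories(
            default_wave_spec("rostrocaudal"), 1, fs=300, seed=0)
        argmax = {lab: float(np.argmax(train.params[lab])) / 300.0
                  for lab in "IJKGH"}
        assert argmax["I"] < argmax["J"] < argmax["K"] < argmax["G"] \
            < argmax["H"]

    def test_zero_amplitudes_give_constant_trajectories(self):
        spec = default_wave_spec("rostrocaudal")
        spec.amplitudes = {k: 0.0 for k in spec.amplitudes}
        spec.jitter_amp_frac = 0.0
        train = generate_wave_trajectories(spec, 2, fs=300, seed=0)
        assert np.allclose(train.params.to_numpy(), 0.0)

    def test_seed_determinism(self):
        a = generate_wave_trajectories(default_wave_spec("caudorostral"),
                                       2, fs=300, seed=42)
        b = generate_wave_trajectories(default_wave_spec("caudorostral"),
                                       2, fs=300, seed=42)
        c = generate_wave_trajectories(default_wave_spec("caudorostral"),
                                       2, fs=300, seed=43)
        assert a.params.equals(b.params)
        assert not a.params.equals(c.params)

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError):
            generate_wave_trajectories(default_wave_spec("rostrocaudal"),
                                       3, fs=300, seed=0, spacing_s=0.1)


@pytest.fixture(scope="module")
def short_recordings():
    """One noise-free and one noisy recording of the same short motion."""
    mech, par, fps = build_catfish_fixture()
    spec = default_wave_spec("rostrocaudal")
    train = generate_wave_trajectories(spec, 1, fs=300, seed=9,
                                       lead_s=0.35, spacing_s=1.2)
    clean = simulate_recording(mech, par, train, fps, noise_mm=0.0, seed=1)
    noisy = simulate_recording(mech, par, train, fps, noise_mm=0.08, seed=1)
    return mech, par, fps, clean, noisy


class TestSimulateRecording:
    def test_noise_free_markers_consistent_with_poses(self, short_recordings):
        mech, par, fps, clean, _ = short_recordings
        tr = clean.markers[0]
        body = tr.body
        local = clean.poses[body][0].inverse().apply(tr.positions[0])
        for f in (10, 100, len(tr.positions) - 1):
            expect = clean.poses[body][f].apply(local)
            assert np.allclose(tr.positions[f], expect, atol=1e-9)

    def test_noise_free_precision_metric_is_zero(self, short_recordings):
        _, _, _, clean, _ = short_recordings
        pm = precision_metric(clean.markers_by_body(), n_frames=40, seed=0)
        assert max(pm.values()) < 1e-9

    def test_noisy_precision_metric_at_noise_scale(self, short_recordings):
        _, _, _, _, noisy = short_recordings
        pm = precision_metric(noisy.markers_by_body(), n_frames=40, seed=0)
        mean_pm = np.mean(list(pm.values()))
        # aligned-configuration RMS for 4 markers sits near 1.2 sigma
        # (3 coordinates per point, 6 of 12 DoFs absorbed by alignment)
        assert 0.7 * 0.08 < mean_pm < 1.6 * 0.08

    def test_seed_determinism(self, short_recordings):
        mech, par, fps, _, noisy = short_recordings
        again = simulate_recording(mech, par, noisy.wave, fps,
                                  noise_mm=0.08, seed=1)
        assert np.allclose(again.markers[3].positions,
                           noisy.markers[3].positions, equal_nan=True)

    def test_missingness_masks_frames(self):
        mech, par, fps = build_catfish_fixture()
        spec = default_wave_spec("rostrocaudal")
        train = generate_wave_trajectories(spec, 1, fs=300, seed=2,
                                           lead_s=0.35)
        rec = simulate_recording(mech, par, train, fps, noise_mm=0.05,
                                 missing_rate=0.1, seed=3)
        frac = np.mean([tr.missing.mean() for tr in rec.markers])
        assert 0.05 < frac < 0.16
        tr = rec.markers[0]
        assert np.isnan(tr.positions[tr.missing]).all()

    def test_ground_truth_includes_settled_lengths(self, short_recordings):
        _, par, _, clean, _ = short_recordings
        assert set(clean.params_true.columns) == set(par.labels)
        assert clean.params_true["B"].std() > 0   # lengths actually moved


class TestParameterRecovery:
    def test_noise_free_round_trip(self, short_recordings):
        # refit the driven DoFs at a handful of frames: machine precision
        mech, par, fps, clean, _ = short_recordings
        bodies = list(clean.marked_bodies)
        free = ["A", "B", "I", "J", "K", "G", "H"]
        sel = np.linspace(40, len(clean.params_true) - 1, 5).astype(int)
        q = None
        for f in sel:
            targets = targets_from_poses(
                {b: clean.poses[b][f] for b in bodies}, fps, bodies)
            fr = fit_mechanism_frame(mech, par, targets, fps, free,
                                     q_init=q, max_nfev=1000)
            q = fr.q
            assert fr.rms < 1e-7
            for lab in free:
                assert fr.params[lab] == pytest.approx(
                    clean.params_true[lab].iloc[f], abs=1e-6)


class TestUnilateralIdentifiability:
    def test_right_side_labels_flagged_by_jacobian_rank(self, catfish):
        # with only left-side (plus midline) bodies observed, the columns of
        # the observation Jacobian for the right-side-only parameters L, M,
        # N vanish on the closure manifold's parameter coordinates
        mech, par, fps = catfish
        from skullkin.fixture import MARKED_BODIES
        conf = forward_kinematics(
            mech, par, dict(par.reference_values(), I=0.1, K=0.08, G=0.05),
            free_labels=("A", "B", "L"))
        st = mech.evaluate(conf.q)
        r, Jloop = mech.closure_residual(st)
        JJ = np.vstack([Jloop, par.matrix])
        unident = []
        for lab in par.labels:
            E = np.zeros(JJ.shape[0])
            E[Jloop.shape[0] + par.index(lab)] = 1.0
            dq = np.linalg.lstsq(JJ, E, rcond=None)[0]
            move = 0.0
            for b in MARKED_BODIES:
                mb = mech._moves[:, mech._lidx[b]].astype(float)
                pts = st.poses[b].apply(fps[b].points)
                for k in range(3):
                    cols = mb[:, None] * (np.cross(st.omega,
                                                   pts[k] - st.anchor)
                                          + st.tdir)
                    move = max(move, float(np.abs(cols.T @ dq).max()))
            unident.append((lab, move))
        flagged = {lab for lab, mv in unident if mv < 1e-8}
        assert {"L", "M", "N"} <= flagged
        assert {"I", "J", "K", "G", "H", "A", "B"}.isdisjoint(flagged)


class TestMakeIndividual:
    def test_unit_scale_default_geometry(self):
        geo, hl = make_individual(1.0)
        assert hl == pytest.approx(76.0)
        assert geo.scale == 1.0

    def test_double_scale_similarity(self):
        geo, hl = make_individual(2.0)
        assert hl == pytest.approx(152.0)
        mech, _, _ = build_catfish_fixture(geo)
        assert mech.census_counts()["mobility"] == 19

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            make_individual(-1.0)

    def test_jittered_individuals_show_jitter_scale_shape_variation(self):
        # landmark deviations from the Procrustes consensus of three
        # individuals track the injected joint-center jitter magnitude
        from skullkin.core import procrustes_consensus
        jitter = 0.9
        shapes = []
        for s in range(3):
            geo, _ = make_individual(1.0, seed=100 + s, jitter_mm=jitter)
            mech, _, _ = build_catfish_fixture(geo, validate=False)
            lm = np.array([j.center for j in mech.joints
                           if "__" not in j.name])
            shapes.append(lm)
        _, devs = procrustes_consensus(shapes)
        rms = float(np.sqrt(np.mean(devs ** 2)))
        # oracle scale: iid jitter on every coordinate of every landmark,
        # partially absorbed by alignment and consensus averaging
        assert 0.4 * jitter < rms < 1.8 * jitter
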