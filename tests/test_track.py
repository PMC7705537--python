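import numpy as np
import pytest

from whiskertrack.parameterize import WhiskerParams
from whiskertrack.track import (
    ParameterScales,
    TrackerConfig,
    TrackingEngine,
    TrackState,
    kalman_predict,
    kalman_update,
    match_whiskers,
    _F,
    _H,
)

from oracles import ReferenceKalman, best_assignment

CFG = TrackerConfig()


def params(rho=100.0, theta=np.pi / 2, b=0.0, length=80.0, frame=-1):
    return WhiskerParams(rho=rho, theta=theta, b=b, length=length, frame_index=frame)


class TestKalman:
    def test_zero_velocity_prediction_is_identity_on_mean(self):
        st = TrackState.from_params(0, params(rho=50.0, theta=1.2), CFG)
        mean_before = st.mean.copy()
        kalman_predict(st, CFG)
        assert np.allclose(st.mean, mean_before)

    def test_covariance_grows_under_prediction(self):
        st = TrackState.from_params(0, params(), CFG)
        for _ in range(5):
            before = np.trace(st.cov)
            kalman_predict(st, CFG)
            assert np.trace(st.cov) > before

    def test_matches_reference_filter_exactly(self):
        """Predict/update recursion agrees with an independently written
        textbook Kalman filter to machine precision."""
        st = TrackState.from_params(0, params(rho=100.0, theta=1.0), CFG)
        ref = ReferenceKalman(
            _F, _H, CFG.process_noise(), CFG.measurement_noise(),
            st.mean.copy(), st.cov.copy(),
        )
        rng = np.random.default_rng(0)
        for k in range(10):
            kalman_predict(st, CFG)
            ref.predict()
            z = [100.0 + k, 1.0 + 0.01 * k, rng.normal(0, 1e-4), 80.0]
            kalman_update(st, params(rho=z[0], theta=z[1], b=z[2], length=z[3]), CFG)
            ref.update(z)
            assert np.allclose(st.mean, ref.x, atol=1e-12)
            assert np.allclose(st.cov, ref.P, atol=1e-12)

    def test_tracks_constant_angular_velocity(self):
        """After convergence the one-step prediction follows theta(t) with a
        small steady-state lag."""
        st = TrackState.from_params(0, params(theta=1.0), CFG)
        theta_dot = 0.01
        errs = []
        for k in range(1, 40):
            kalman_predict(st, CFG)
            true_theta = 1.0 + theta_dot * k
            errs.append(abs(st.mean[1] - true_theta))
            kalman_update(st, params(theta=true_theta), CFG)
        assert np.mean(errs[-10:]) < 2e-3


class TestMatch:
    def test_identical_sets_give_identity_assignment(self):
        preds = {i: params(rho=50.0 + 40 * i) for i in range(5)}
        dets = [params(rho=50.0 + 40 * i) for i in range(5)]
        matches, lost, orphans = match_whiskers(preds, dets, CFG)
        assert matches == {i: i for i in range(5)}
        assert not lost and not orphans

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_recovers_permutation_against_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        preds = {
            i: params(rho=40.0 + 45 * i, theta=1.0 + 0.12 * i, length=80 + 6 * i)
            for i in range(n)
        }
        perm = rng.permutation(n)
        dets = [
            params(
                rho=preds[int(k)].rho + rng.normal(0, 1.0),
                theta=preds[int(k)].theta + rng.normal(0, 0.005),
                length=preds[int(k)].length + rng.normal(0, 0.5),
            )
            for k in perm
        ]
        ps = ParameterScales()
        for i, w in preds.items():
            ps.add(0, w)
        scales = ps.stds()
        matches, _, _ = match_whiskers(preds, dets, CFG, scales)
        expected = {int(k): j for j, k in enumerate(perm)}
        assert matches == expected
        # brute-force oracle agrees on the optimal assignment
        P = np.vstack([ParameterScales.vector(preds[i]) for i in range(n)]) / scales
        D = np.vstack([ParameterScales.vector(d) for d in dets]) / scales
        cost = np.linalg.norm(P[:, None] - D[None, :], axis=2)
        _, perm_star = best_assignment(cost)
        assert {i: perm_star[i] for i in range(n)} == matches

    def test_missing_detection_lands_in_lost_set(self):
        preds = {i: params(rho=50.0 + 50 * i) for i in range(4)}
        dets = [params(rho=50.0 + 50 * i) for i in (0, 1, 3)]
        matches, lost, orphans = match_whiskers(preds, dets, CFG)
        assert lost == [2]
        assert not orphans
        assert len(matches) == 3

    def test_outrageous_cost_rejected(self):
        preds = {0: params(rho=10.0)}
        dets = [params(rho=500.0)]
        matches, lost, orphans = match_whiskers(preds, dets, CFG)
        assert not matches and lost == [0] and orphans == [0]


def truth_stream(truth, frame, rng, drop=(), sigma=(0.3, 0.002, 5e-5, 0.5)):
    """Detections for one frame from ground truth + measurement noise, in a
    deterministic shuffled order."""
    dets = []
    for k in range(truth.n_whiskers):
        if k in drop or not truth.visible[frame, k]:
            continue
        rho, theta, b, length = truth.params[frame, k]
        dets.append(
            WhiskerParams(
                rho=rho + rng.normal(0, sigma[0]),
                theta=theta + rng.normal(0, sigma[1]),
                b=b + rng.normal(0, sigma[2]),
                length=length + rng.normal(0, sigma[3]),
                frame_index=frame,
            )
        )
    order = rng.permutation(len(dets))
    return [dets[i] for i in order]


class TestEngine:
    def test_static_whiskers_keep_frame0_labels(self):
        engine = TrackingEngine(TrackerConfig(bootstrap_len=10))
        base = [params(rho=40.0 + 50 * i, theta=1.0 + 0.1 * i) for i in range(5)]
        for frame in range(30):
            out = engine.step(list(base))
            assert set(out) == set(range(5))
            for ident, w in out.items():
                assert w.rho == pytest.approx(40.0 + 50 * ident)

    def test_bootstrap_len_one_training_set_is_frame_zero(self):
        engine = TrackingEngine(TrackerConfig(bootstrap_len=1))
        engine.step([params(rho=30.0), params(rho=90.0)])
        assert set(engine.window.frames) == {0}
        assert sorted(engine.window.labels) == [0, 1]

    def test_bootstrap_on_slow_whisking(self, small_scene):
        """Slow sinusoidal whisking: >= 99% of bootstrap labels match the
        generator's whisker order."""
        _, truth, cfg = small_scene
        engine = TrackingEngine(TrackerConfig(bootstrap_len=60))
        rng = np.random.default_rng(3)
        correct = total = 0
        for frame in range(60):
            out = engine.step(truth_stream(truth, frame, rng))
            for ident, w in out.items():
                k = int(np.argmin(np.abs(truth.params[frame, :, 0] - w.rho)))
                total += 1
                correct += k == ident
        assert total >= 200
        assert correct / total >= 0.99

    def test_output_never_exceeds_identities_and_is_exclusive(self, small_scene):
        _, truth, cfg = small_scene
        engine = TrackingEngine(TrackerConfig(bootstrap_len=5, retrain_every=10))
        rng = np.random.default_rng(5)
        for frame in range(80):
            # a spurious detection every frame after the identity-defining
            # first frame must never create a new identity
            extra = (
                [params(rho=500.0, theta=2.2, length=60.0, frame=frame)]
                if frame > 0
                else []
            )
            out = engine.step(truth_stream(truth, frame, rng) + extra)
            assert len(out) <= truth.n_whiskers
            ids = list(out.values())
            assert len({id(w) for w in ids}) == len(ids)

    def test_no_orphans_means_no_recoveries(self):
        engine = TrackingEngine(TrackerConfig(bootstrap_len=2, retrain_every=2))
        base = [params(rho=40.0 + 50 * i) for i in range(3)]
        for _ in range(10):
            engine.step(list(base))
        assert not any(e["event"] == "recovered" for e in engine.events)

    def test_occlusion_recovered_on_reappearance(self, small_scene):
        """A whisker hidden for 20 frames is re-acquired with its original
        identity within 2 frames of reappearing, and its position is only
        estimated (not output) while hidden."""
        _, truth, cfg = small_scene
        engine = TrackingEngine(
            TrackerConfig(bootstrap_len=20, retrain_every=10)
        )
        rng = np.random.default_rng(7)
        n_frames = truth.n_frames
        occluded = range(50, 70)
        hidden_id = None
        for frame in range(n_frames):
            drop = (2,) if frame in occluded else ()
            out = engine.step(truth_stream(truth, frame, rng, drop=drop))
            if frame == 49:
                # find the engine identity tracking truth whisker 2
                hidden_id = min(
                    out,
                    key=lambda i: abs(out[i].rho - truth.params[frame, 2, 0]),
                )
            if frame in occluded:
                assert hidden_id not in out
            if frame >= 72 and frame < 90:
                assert hidden_id in out
                assert abs(out[hidden_id].rho - truth.params[frame, 2, 0]) < 5
        est_frames = [
            e["frame"]
            for e in engine.events
            if e["event"] == "estimated" and e.get("identity") == hidden_id
        ]
        assert set(occluded) <= set(est_frames)

    def test_injected_jump_flagged_and_excluded(self, small_scene):
        _, truth, cfg = small_scene
        engine = TrackingEngine(TrackerConfig(bootstrap_len=10, retrain_every=10))
        rng = np.random.default_rng(9)
        jump_frame = 40
        for frame in range(60):
            dets = truth_stream(truth, frame, rng)
            if frame == jump_frame:
                w = dets[0]
                dets[0] = WhiskerParams(
                    rho=w.rho,
                    theta=w.theta + np.deg2rad(14),
                    b=w.b,
                    length=w.length,
                    frame_index=frame,
                )
            engine.step(dets)
        flags = [e for e in engine.events if e["event"] == "fp_flagged"
                 and e["frame"] == jump_frame]
        assert flags
        flagged_id = flags[0]["identity"]
        assert not any(
            f == jump_frame and lab == flagged_id
            for f, lab in zip(engine.window.frames, engine.window.labels)
        )
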