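"""Frame-to-frame whisker tracking with recognition and expert correction.

The tracked identities are fixed at the first frame: whatever whiskers are
visible there define the N labels, and no new identities are created later.
Tracking runs in two regimes:

* **Bootstrap** -- for a user-configurable number of initial frames each
  identity is followed purely by a Kalman filter over its parameter vector
  (constant velocity in rho and theta, random walk in b and L) with optimal
  one-to-one assignment between predictions and detections.  The labelled
  parameter vectors collected here seed the recogniser's training window.

* **Recognition** -- after bootstrap, each frame is processed in a fixed
  order: the one-vs-one SVM classifier proposes identities first; the
  N-expert then rejects physically impossible frame-to-frame jumps (removing
  them from both the output and the training data); finally the Kalman
  tracker acts as P-expert, matching still-unassigned ("orphan") detections
  to the predictions of identities the classifier missed.  An identity found
  by neither keeps a coasting prediction, flagged "estimated", which is not
  part of the output but lets the P-expert re-acquire the whisker when it
  reappears (e.g. after an occlusion).

The per-frame interface consumes plain lists of fitted
:class:`~whiskertrack.parameterize.WhiskerParams`, so the engine can be
driven by the full video pipeline or directly by synthetic detection
streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .parameterize import WhiskerParams
from .recognize import (
    RecognizerConfig,
    TrainingWindow,
    OneVsOneSVM,
    build_features,
    n_expert,
    train_classifier,
)

__all__ = [
    "TrackerConfig",
    "TrackState",
    "kalman_predict",
    "kalman_update",
    "match_whiskers",
    "ParameterScales",
    "TrackingEngine",
]

# state layout: (rho, theta, rho_dot, theta_dot, b, L)
_F = np.eye(6)
_F[0, 2] = 1.0
_F[1, 3] = 1.0
_H = np.zeros((4, 6))
_H[0, 0] = 1.0  # rho
_H[1, 1] = 1.0  # theta
_H[2, 4] = 1.0  # b
_H[3, 5] = 1.0  # L


@dataclass
class TrackerConfig:
    bootstrap_len: int = 50
    retrain_every: int = 25  # the "s" cadence
    window: int = 2000  # the training window "W" (frames)
    assign_max_cost: float = 3.0  # normalised units
    max_dtheta: float = np.deg2rad(10.0)  # per frame
    max_drho: float = 15.0  # px per frame
    max_coast: int = 100  # frames a lost track keeps predicting
    # process noise: white-acceleration std for (rho, theta), random-walk
    # std for (b, L), all per frame
    q_rho: float = 0.1
    q_theta: float = 2e-3
    q_b: float = 5e-5
    q_len: float = 0.5
    # measurement noise stds for (rho, theta, b, L)
    r_rho: float = 0.5
    r_theta: float = 0.004
    r_b: float = 1e-4
    r_len: float = 1.0

    def __post_init__(self):
        for name in ("bootstrap_len", "retrain_every", "window", "assign_max_cost",
                     "max_dtheta", "max_drho", "max_coast"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def process_noise(self) -> np.ndarray:
        Q = np.zeros((6, 6))
        for pos, vel, a in ((0, 2, self.q_rho), (1, 3, self.q_theta)):
            a2 = a * a
            Q[pos, pos] += 0.25 * a2
            Q[pos, vel] = Q[vel, pos] = 0.5 * a2
            Q[vel, vel] = a2
        Q[4, 4] = self.q_b**2
        Q[5, 5] = self.q_len**2
        return Q

    def measurement_noise(self) -> np.ndarray:
        return np.diag(
            [self.r_rho**2, self.r_theta**2, self.r_b**2, self.r_len**2]
        )


@dataclass
class TrackState:
    """Per-identity Kalman state and bookkeeping."""

    identity: int
    mean: np.ndarray  # (6,)
    cov: np.ndarray  # (6, 6)
    status: str = "tracked"  # tracked | lost | estimated
    last_seen: int = 0
    coast: int = 0

    @classmethod
    def from_params(
        cls, identity: int, w: WhiskerParams, cfg: TrackerConfig, frame: int = 0
    ) -> "TrackState":
        mean = np.array([w.rho, w.theta, 0.0, 0.0, w.b, w.length])
        cov = np.diag(
            [
                cfg.r_rho**2,
                cfg.r_theta**2,
                (5 * cfg.q_rho) ** 2,
                (5 * cfg.q_theta) ** 2,
                cfg.r_b**2,
                cfg.r_len**2,
            ]
        )
        return cls(identity, mean, cov, last_seen=frame)

    def predicted_params(self, frame: int = -1) -> WhiskerParams:
        rho, theta, _, _, b, length = self.mean
        eps = 1e-3
        return WhiskerParams(
            rho=float(rho),
            theta=float(np.clip(theta, eps, np.pi - eps)),
            b=float(b),
            length=float(max(length, 1.0)),
            frame_index=frame,
        )


def kalman_predict(state: TrackState, cfg: TrackerConfig) -> TrackState:
    """One constant-velocity prediction step (in place), returning state."""
    state.mean = _F @ state.mean
    state.cov = _F @ state.cov @ _F.T + cfg.process_noise()
    return state


def kalman_update(state: TrackState, w: WhiskerParams, cfg: TrackerConfig) -> TrackState:
    z = np.array([w.rho, w.theta, w.b, w.length])
    R = cfg.measurement_noise()
    S = _H @ state.cov @ _H.T + R
    K = state.cov @ _H.T @ np.linalg.inv(S)
    state.mean = state.mean + K @ (z - _H @ state.mean)
    state.cov = (np.eye(6) - K @ _H) @ state.cov
    return state


class ParameterScales:
    """Running standard deviations of (rho, cot_theta, b, L) used to
    normalise assignment costs; floored so no axis collapses."""

    FLOORS = np.array([1.0, 0.05, 1e-4, 1.0])

    def __init__(self, window: int = 2000):
        self.window = window
        self._buffer: list[tuple[int, np.ndarray]] = []

    @staticmethod
    def vector(w: WhiskerParams) -> np.ndarray:
        return np.array([w.rho, w.cot_theta, w.b, w.length])

    def add(self, frame: int, w: WhiskerParams) -> None:
        self._buffer.append((frame, self.vector(w)))

    def prune(self, frame: int) -> None:
        lo = frame - self.window
        self._buffer = [(f, v) for f, v in self._buffer if f >= lo]

    def stds(self) -> np.ndarray:
        if len(self._buffer) < 4:
            return self.FLOORS.copy()
        arr = np.vstack([v for _, v in self._buffer])
        return np.maximum(arr.std(axis=0), self.FLOORS)


def match_whiskers(
    predictions: dict[int, WhiskerParams],
    detections: list[WhiskerParams],
    cfg: TrackerConfig,
    scales: np.ndarray | None = None,
):
    """Optimal one-to-one assignment between predictions and detections.

    Cost is the Euclidean norm of the (rho, cot_theta, b, L) difference with
    each axis scaled by its running std; pairs costing more than
    ``assign_max_cost`` are rejected.  Returns ``(matches, lost, orphans)``
    where matches maps identity -> detection index.
    """
    ids = sorted(predictions)
    if not ids or not detections:
        return {}, list(ids), list(range(len(detections)))
    if scales is None:
        scales = ParameterScales.FLOORS
    P = np.vstack([ParameterScales.vector(predictions[i]) for i in ids]) / scales
    D = np.vstack([ParameterScales.vector(d) for d in detections]) / scales
    cost = np.linalg.norm(P[:, None, :] - D[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    matches: dict[int, int] = {}
    for r, c in zip(rows, cols):
        if cost[r, c] <= cfg.assign_max_cost:
            matches[ids[r]] = int(c)
    lost = [i for i in ids if i not in matches]
    orphans = [j for j in range(len(detections)) if j not in matches.values()]
    return matches, lost, orphans


class TrackingEngine:
    """Stateful tracker consuming per-frame detection lists.

    Call :meth:`step` once per frame in order, starting at frame 0 (which
    defines the identities).  Returns the accepted output for that frame as
    ``{identity: WhiskerParams}``.
    """

    def __init__(
        self,
        cfg: TrackerConfig | None = None,
        recog_cfg: RecognizerConfig | None = None,
    ):
        self.cfg = cfg or TrackerConfig()
        self.recog_cfg = recog_cfg or RecognizerConfig()
        self.n_identities = 0
        self.states: dict[int, TrackState] = {}
        self.window = TrainingWindow(self.cfg.window)
        self.scales = ParameterScales(self.cfg.window)
        self.ensemble: OneVsOneSVM | None = None
        self.prev_output: dict[int, WhiskerParams] = {}
        self.prev_means: tuple[float, float] = (0.0, 0.0)
        self.events: list[dict] = []
        self.frame = -1

    # -- helpers ---------------------------------------------------------

    def _log(self, event: str, identity=None, **extra) -> None:
        rec = {"frame": self.frame, "event": event}
        if identity is not None:
            rec["identity"] = int(identity)
        rec.update(extra)
        self.events.append(rec)

    def _accept(self, identity: int, det: WhiskerParams, feats: np.ndarray,
                out: dict) -> None:
        out[identity] = det
        st = self.states[identity]
        kalman_update(st, det, self.cfg)
        st.status = "tracked"
        st.coast = 0
        st.last_seen = self.frame
        self.window.add(self.frame, identity, feats)
        self.scales.add(self.frame, det)

    def _plausible(self, identity: int, det: WhiskerParams) -> bool:
        """N-expert gate against the identity's previous-frame output."""
        prev = self.prev_output.get(identity)
        if prev is None:
            return True
        return not n_expert(det, prev, self.cfg.max_dtheta, self.cfg.max_drho)

    def _predict_all(self) -> dict[int, WhiskerParams]:
        preds = {}
        for i, st in self.states.items():
            if st.status == "lost" and st.coast >= self.cfg.max_coast:
                continue  # frozen: variance would diverge
            kalman_predict(st, self.cfg)
            preds[i] = st.predicted_params(self.frame)
        return preds

    # -- main loop -------------------------------------------------------

    def step(self, detections: list[WhiskerParams]) -> dict[int, WhiskerParams]:
        self.frame += 1
        if self.frame == 0:
            return self._start(detections)
        preds = self._predict_all()
        if self.frame <= self.cfg.bootstrap_len or self.ensemble is None:
            out = self._bootstrap_step(preds, detections)
        else:
            out = self._recognition_step(preds, detections)
        # identities absent from the output coast as "estimated"
        for i, st in self.states.items():
            if i in out:
                continue
            if st.status != "lost":
                st.status = "lost"
                self._log("lost", i)
            st.coast += 1
            if st.coast <= self.cfg.max_coast:
                self._log("estimated", i)
        if out:
            rhos = [w.rho for w in out.values()]
            cots = [w.cot_theta for w in out.values()]
            self.prev_means = (float(np.mean(rhos)), float(np.mean(cots)))
        self.prev_output = dict(out)
        self.window.prune(self.frame)
        self.scales.prune(self.frame)
        if (
            self.frame >= self.cfg.bootstrap_len
            and self.frame % self.cfg.retrain_every == 0
            and len(self.window)
        ):
            ens = train_classifier(self.window, self.recog_cfg)
            if len(ens.classes_):
                self.ensemble = ens
                self._log(
                    "retrain",
                    ensemble_size=ens.ensemble_size,
                    excluded=list(ens.excluded_),
                )
            else:
                # no identity has enough samples yet: keep Kalman tracking
                self._log("retrain_skipped")
        return out

    def _start(self, detections: list[WhiskerParams]) -> dict[int, WhiskerParams]:
        order = np.argsort([d.rho for d in detections])
        out: dict[int, WhiskerParams] = {}
        rhos = [d.rho for d in detections]
        cots = [d.cot_theta for d in detections]
        means = (float(np.mean(rhos)), float(np.mean(cots))) if detections else (0.0, 0.0)
        for ident, di in enumerate(order):
            det = detections[int(di)]
            self.states[ident] = TrackState.from_params(ident, det, self.cfg)
            out[ident] = det
            feats = build_features(det, means)
            self.window.add(0, ident, feats)
            self.scales.add(0, det)
            self._log("matched", ident)
        self.n_identities = len(out)
        self.prev_output = dict(out)
        self.prev_means = means
        return out

    def _bootstrap_step(self, preds, detections) -> dict[int, WhiskerParams]:
        out: dict[int, WhiskerParams] = {}
        matches, lost, orphans = match_whiskers(
            preds, detections, self.cfg, self.scales.stds()
        )
        for ident, di in matches.items():
            det = detections[di]
            if not self._plausible(ident, det):
                self._log(
                    "fp_flagged", ident, stage="bootstrap",
                    rho=det.rho, theta=det.theta,
                )
                continue
            feats = build_features(det, self.prev_means)
            self._accept(ident, det, feats, out)
            self._log("matched", ident)
        return out

    def _recognition_step(self, preds, detections) -> dict[int, WhiskerParams]:
        out: dict[int, WhiskerParams] = {}
        feats = [build_features(d, self.prev_means) for d in detections]
        # 1) classifier proposes identities
        claims: dict[int, list[tuple[int, int]]] = {}
        for di, f in enumerate(feats):
            ident, margin = self.ensemble.classify(f)
            claims.setdefault(ident, []).append((-margin, di))
        orphan_pool: set[int] = set()
        classified: dict[int, int] = {}
        for ident, lst in claims.items():
            lst.sort()
            classified[ident] = lst[0][1]
            for _, di in lst[1:]:
                orphan_pool.add(di)
        # 2) N-expert validates the classifier's proposals
        for ident, di in list(classified.items()):
            det = detections[di]
            if not self._plausible(ident, det):
                # flagged detections never reach the window or the output
                self._log("fp_flagged", ident, rho=det.rho, theta=det.theta)
                orphan_pool.add(di)
                del classified[ident]
        for ident, di in classified.items():
            self._accept(ident, detections[di], feats[di], out)
            self._log("classified", ident)
        # 3) tracker as P-expert recovers the rest
        open_ids = {
            i: preds[i] for i in preds if i not in out
        }
        orphans = sorted(orphan_pool)
        matches, _, _ = match_whiskers(
            open_ids,
            [detections[j] for j in orphans],
            self.cfg,
            self.scales.stds(),
        )
        for ident, oi in matches.items():
            di = orphans[oi]
            det = detections[di]
            if not self._plausible(ident, det):
                self._log(
                    "fp_flagged", ident, stage="p_expert",
                    rho=det.rho, theta=det.theta,
                )
                continue
            self._accept(ident, det, feats[di], out)
            self._log("recovered", ident)
        return out
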