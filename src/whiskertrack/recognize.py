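"""Appearance-based whisker recognition and expert validation.

A whisker's identity is recognised from a 6-D feature vector built from its
fitted parameters: length ``L``, bending ``b``, base position ``rho``,
``cot(theta)``, and the offsets of ``rho`` and ``cot(theta)`` from the
previous frame's across-whisker means (the previous frame is used because
the current frame's means are only reliable once all whiskers are
identified).  ``cot(theta)`` rather than ``theta`` enters because a whisker
rotating about a fixed hidden pivot R behind the snout line obeys

    rho = L_f * cot(theta) + rho_f,

a straight line in (cot(theta), rho) space whose slope is the pivot depth
``L_f`` and intercept the pivot foot ``rho_f`` -- so the pair carries a
stable, whisker-specific signature.

Classification is a one-vs-one ensemble of N(N-1)/2 linear soft-margin SVMs
on features standardised over a sliding training window, retrained every
``s`` frames.  Two "expert" processes curate the training data: the N-expert
rejects physically impossible frame-to-frame position changes (false
positives), and the tracker acting as P-expert recovers unmatched detections
(false negatives, in :mod:`whiskertrack.track`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVC

from .parameterize import WhiskerParams

__all__ = [
    "RecognizerConfig",
    "build_features",
    "TrainingWindow",
    "OneVsOneSVM",
    "train_classifier",
    "n_expert",
    "PivotEstimate",
    "estimate_pivot",
]

N_FEATURES = 6


@dataclass
class RecognizerConfig:
    svm_c: float = 1.0
    min_train_samples: int = 20
    min_pivot_samples: int = 50
    min_theta_range: float = np.deg2rad(10.0)


def build_features(
    w: WhiskerParams, prev_means: tuple[float, float]
) -> np.ndarray:
    """Feature vector (L, b, rho, cot_theta, d_rho, d_cot).

    ``prev_means`` are the across-whisker means of (rho, cot_theta) from the
    previous frame; on frame 0 the caller passes the current frame's means.
    """
    cot = w.cot_theta
    return np.array(
        [w.length, w.b, w.rho, cot, w.rho - prev_means[0], cot - prev_means[1]]
    )


class TrainingWindow:
    """Sliding window of labelled feature vectors from frames n-W to n.

    Samples flagged by an expert are removed permanently; the window is the
    sole source of classifier training data, so expert hygiene here is what
    keeps recognition from degrading over long runs.
    """

    def __init__(self, window: int = 2000):
        self.window = int(window)
        self.frames: list[int] = []
        self.labels: list[int] = []
        self.features: list[np.ndarray] = []

    def add(self, frame: int, label: int, features: np.ndarray) -> None:
        self.frames.append(int(frame))
        self.labels.append(int(label))
        self.features.append(np.asarray(features, float))

    def remove(self, frame: int, label: int) -> int:
        """Drop all samples for (frame, label); returns how many were cut."""
        keep = [
            i
            for i in range(len(self.frames))
            if not (self.frames[i] == frame and self.labels[i] == label)
        ]
        removed = len(self.frames) - len(keep)
        if removed:
            self.frames = [self.frames[i] for i in keep]
            self.labels = [self.labels[i] for i in keep]
            self.features = [self.features[i] for i in keep]
        return removed

    def prune(self, current_frame: int) -> None:
        lo = current_frame - self.window
        if self.frames and self.frames[0] < lo:
            start = next(
                i for i, f in enumerate(self.frames) if f >= lo
            )
            self.frames = self.frames[start:]
            self.labels = self.labels[start:]
            self.features = self.features[start:]

    def __len__(self) -> int:
        return len(self.frames)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.frames:
            return np.empty((0, N_FEATURES)), np.empty(0, int)
        return np.vstack(self.features), np.asarray(self.labels, int)


class OneVsOneSVM:
    """One-vs-one ensemble of linear soft-margin SVMs with majority vote.

    Features are standardised to zero mean and unit variance using the
    training-window statistics.  Vote ties are resolved by the smaller
    standardised distance to the class centroid.
    """

    def __init__(self, C: float = 1.0):
        self.C = C
        self.pairs: dict[tuple[int, int], LinearSVC] = {}
        self.classes_: np.ndarray = np.empty(0, int)
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None
        self.centroids_: dict[int, np.ndarray] = {}

    @property
    def ensemble_size(self) -> int:
        return len(self.pairs)

    def fit(
        self, X: np.ndarray, y: np.ndarray, min_samples: int = 1
    ) -> "OneVsOneSVM":
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        self.std_ = np.where(std > 1e-12, std, 1.0)
        Z = (X - self.mean_) / self.std_
        counts = {c: int((y == c).sum()) for c in np.unique(y)}
        self.classes_ = np.array(
            [c for c, n in counts.items() if n >= min_samples], int
        )
        self.excluded_ = sorted(set(counts) - set(self.classes_.tolist()))
        self.centroids_ = {c: Z[y == c].mean(axis=0) for c in self.classes_}
        self.pairs = {}
        weights, intercepts, pair_labels = [], [], []
        for a_i in range(len(self.classes_)):
            for b_i in range(a_i + 1, len(self.classes_)):
                a, b = int(self.classes_[a_i]), int(self.classes_[b_i])
                sel = (y == a) | (y == b)
                clf = LinearSVC(C=self.C, dual=False)
                clf.fit(Z[sel], y[sel])
                self.pairs[(a, b)] = clf
                weights.append(clf.coef_[0])
                intercepts.append(clf.intercept_[0])
                pair_labels.append((a, b))
        # flat copies of the hyperplanes so voting is a single matrix product
        if pair_labels:
            self._W = np.asarray(weights)
            self._b = np.asarray(intercepts)
            self._pair_labels = np.asarray(pair_labels, int)
        else:
            self._W = np.zeros((0, Z.shape[1]))
            self._b = np.zeros(0)
            self._pair_labels = np.zeros((0, 2), int)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.mean_) / self.std_

    def classify(self, features: np.ndarray) -> tuple[int, int]:
        """Majority vote -> (identity, margin = top votes - runner-up)."""
        if len(self.classes_) == 0:
            raise RuntimeError("ensemble is not trained")
        if len(self.classes_) == 1:
            return int(self.classes_[0]), 0
        z = self.transform(features)
        votes = {int(c): 0 for c in self.classes_}
        scores = self._W @ z + self._b  # sign decides each pairwise vote
        winners = np.where(scores > 0, self._pair_labels[:, 1], self._pair_labels[:, 0])
        for w in winners:
            votes[int(w)] += 1
        ranked = sorted(votes.items(), key=lambda kv: -kv[1])
        top_votes = ranked[0][1]
        tied = [c for c, v in votes.items() if v == top_votes]
        if len(tied) > 1:
            tied.sort(key=lambda c: float(np.linalg.norm(z - self.centroids_[c])))
        winner = tied[0]
        runner_up = ranked[1][1] if len(ranked) > 1 else 0
        return winner, top_votes - runner_up


def train_classifier(
    window: TrainingWindow, cfg: RecognizerConfig | None = None
) -> OneVsOneSVM:
    """Fit the one-vs-one ensemble on the current training window.

    Identities with fewer than ``min_train_samples`` examples are excluded
    from this training cycle (recorded on the returned ensemble)."""
    cfg = cfg or RecognizerConfig()
    X, y = window.arrays()
    if len(X) == 0:
        raise ValueError("empty training window")
    return OneVsOneSVM(C=cfg.svm_c).fit(X, y, min_samples=cfg.min_train_samples)


def n_expert(
    candidate: WhiskerParams,
    prev: WhiskerParams,
    max_dtheta: float,
    max_drho: float,
) -> bool:
    """True when the frame-to-frame change is physically impossible.

    A whisker cannot move more than the configured per-frame limits between
    consecutive frames; strictly exceeding either limit marks the detection
    a false positive (values exactly at threshold pass).
    """
    return (
        abs(candidate.theta - prev.theta) > max_dtheta
        or abs(candidate.rho - prev.rho) > max_drho
    )


@dataclass
class PivotEstimate:
    rho_f: float
    L_f: float
    r2: float
    n_samples: int
    degenerate: bool = False


def estimate_pivot(
    rho: np.ndarray,
    theta: np.ndarray,
    cfg: RecognizerConfig | None = None,
) -> PivotEstimate:
    """Recover the hidden pivot point from (rho, theta) samples.

    Ordinary least squares of rho on cot(theta); the slope is the pivot
    depth L_f below the snout line and the intercept the pivot foot rho_f.
    With no usable spread in theta the slope is unidentifiable and a
    degenerate estimate (rho_f = mean rho) is returned.
    """
    cfg = cfg or RecognizerConfig()
    rho = np.asarray(rho, float)
    theta = np.asarray(theta, float)
    if len(rho) < 2 or len(rho) != len(theta):
        raise ValueError("need matching rho/theta samples (>= 2)")
    cot = 1.0 / np.tan(theta)
    if (
        len(rho) < cfg.min_pivot_samples
        or float(np.ptp(theta)) < cfg.min_theta_range
        or float(np.std(cot)) < 1e-12
    ):
        return PivotEstimate(
            rho_f=float(np.mean(rho)),
            L_f=float("nan"),
            r2=float("nan"),
            n_samples=len(rho),
            degenerate=True,
        )
    res = stats.linregress(cot, rho)
    return PivotEstimate(
        rho_f=float(res.intercept),
        L_f=float(res.slope),
        r2=float(res.rvalue**2),
        n_samples=len(rho),
    )
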