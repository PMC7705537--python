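"""End-to-end orchestration: frames in, parameter traces out.

The processing chain per frame is: background subtraction and silhouette
removal -> sub-pixel centerline detection -> clustering/stitching ->
parameter fitting -> tracking with recognition and expert correction.
Deterministic given the same frames and configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .centerline import (
    compute_derivatives,
    detect_centerline_points,
    strength_quantile,
)
from .cluster import ClusterConfig, extract_whiskers
from .parameterize import FitConfig, SnoutLine, WhiskerParams, fit_whisker
from .preprocess import Preprocessor, SilhouetteConfig
from .recognize import RecognizerConfig
from .trace import TraceTable
from .track import TrackerConfig, TrackingEngine

__all__ = ["DetectionConfig", "WhiskerPipeline", "run_pipeline"]


@dataclass
class DetectionConfig:
    sigma: float = 1.5  # Gaussian-derivative scale (px)
    min_strength: float | None = 4.0  # None -> quantile calibration
    strength_quantile: float = 0.99
    min_theta: float = np.deg2rad(10.0)  # reject near-snout-parallel fits
    min_points: int = 5


class WhiskerPipeline:
    """Library face of the tracker; see :func:`run_pipeline` for file I/O."""

    def __init__(
        self,
        snout: SnoutLine,
        fps: float = 1000.0,
        preprocessor: Preprocessor | None = None,
        detection: DetectionConfig | None = None,
        cluster_cfg: ClusterConfig | None = None,
        fit_cfg: FitConfig | None = None,
        tracker_cfg: TrackerConfig | None = None,
        recognizer_cfg: RecognizerConfig | None = None,
    ):
        self.snout = snout
        self.fps = fps
        self.preprocessor = preprocessor or Preprocessor(
            silhouette=SilhouetteConfig(open_radius=3), snout=snout, side_margin=8.0
        )
        self.detection = detection or DetectionConfig()
        self.cluster_cfg = cluster_cfg or ClusterConfig()
        self.fit_cfg = fit_cfg or FitConfig()
        self.tracker_cfg = tracker_cfg or TrackerConfig()
        self.recognizer_cfg = recognizer_cfg or RecognizerConfig()
        self._min_strength: float | None = None

    def calibrate(self, frames) -> None:
        """Fit the background model; calibrate the ridge-strength threshold
        on the first frame when none is configured."""
        self.preprocessor.fit(frames)
        if self.detection.min_strength is not None:
            self._min_strength = float(self.detection.min_strength)
        else:
            clean0 = self.preprocessor(frames[0])
            derivs = compute_derivatives(clean0, self.detection.sigma)
            self._min_strength = strength_quantile(
                derivs, self.detection.strength_quantile
            )

    def detect_frame(self, frame, frame_index: int = -1) -> list[WhiskerParams]:
        """Cleaned frame -> fitted whisker candidates for one frame."""
        if self._min_strength is None:
            raise RuntimeError("call calibrate() first")
        clean = self.preprocessor(frame)
        derivs = compute_derivatives(clean, self.detection.sigma)
        points = detect_centerline_points(derivs, self._min_strength)
        # a whisker counts as snout-attached if its base reaches the cut
        # boundary: allow for the side margin plus the detector's ~3 sigma
        # edge zone where ridge points cannot form
        clusters = extract_whiskers(
            points,
            self.cluster_cfg,
            self.snout,
            attach_margin=self.preprocessor.side_margin + 3.0 * self.detection.sigma,
        )
        out = []
        for c in clusters:
            if len(c) < self.detection.min_points:
                continue
            try:
                params = fit_whisker(c, self.snout, self.fit_cfg, frame_index)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not params.converged:
                continue
            if not (
                self.detection.min_theta
                <= params.theta
                <= np.pi - self.detection.min_theta
            ):
                continue
            out.append(params)
        return out

    def run(self, frames, progress: bool = False):
        """Process a whole video; returns ``(TraceTable, report)``."""
        self.calibrate(frames)
        engine = TrackingEngine(self.tracker_cfg, self.recognizer_cfg)
        n_frames = len(frames)
        trace: TraceTable | None = None
        iterator = range(n_frames)
        if progress:
            try:
                from tqdm import tqdm

                iterator = tqdm(iterator, desc="tracking", unit="frame")
            except ImportError:
                pass
        for fi in iterator:
            detections = self.detect_frame(frames[fi], fi)
            out = engine.step(detections)
            if trace is None:
                trace = TraceTable.empty(
                    n_frames,
                    engine.n_identities,
                    fps=self.fps,
                    provenance={"tracker": "whiskertrack"},
                )
            for ident, w in out.items():
                trace.set(fi, ident, w.as_array())
        if trace is None:
            trace = TraceTable.empty(n_frames, 0, fps=self.fps)
        report = {
            "n_frames": n_frames,
            "n_identities": trace.n_identities,
            "min_strength": self._min_strength,
            "event_counts": _count_events(engine.events),
        }
        return trace, report, engine


def _count_events(events: list[dict]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for e in events:
        counts[e["event"]] = counts.get(e["event"], 0) + 1
    return counts


def run_pipeline(cfg) -> TraceTable:
    """Run from a :class:`~whiskertrack.config.RunConfig`; writes the trace
    (HDF5 + CSV mirror), a JSON run report and a JSON-lines event log into
    the configured output directory and returns the trace."""
    from .io import read_video
    from .metrics import whiskers_per_frame

    if cfg.synthetic_preset:
        from .synthetic import benchmark_scene, generate_scene

        if cfg.synthetic_preset not in ("benchmark-B",):
            raise ValueError(f"unknown preset {cfg.synthetic_preset!r}")
        frames, _ = generate_scene(benchmark_scene(seed=cfg.seed))
        snout = frames.cfg.snout
        fps = frames.cfg.fps
    elif cfg.video:
        frames = read_video(cfg.video)
        snout = cfg.snout
        fps = cfg.fps
    else:
        raise ValueError("config names neither a video nor a synthetic preset")

    pre = Preprocessor(
        n_samples=cfg.background_samples,
        silhouette=cfg.silhouette,
        snout=snout,
        invert=cfg.invert,
        side_margin=cfg.side_margin,
    )
    pipe = WhiskerPipeline(
        snout,
        fps=fps,
        preprocessor=pre,
        detection=cfg.detection,
        cluster_cfg=cfg.cluster,
        fit_cfg=cfg.fit,
        tracker_cfg=cfg.track,
        recognizer_cfg=cfg.recognize,
    )
    trace, report, engine = pipe.run(frames, progress=cfg.progress)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    trace.to_hdf5(outdir / "traces.h5")
    trace.to_csv(outdir / "traces.csv")
    _, mean, std, _ = whiskers_per_frame(trace)
    report["whiskers_per_frame_mean"] = mean
    report["whiskers_per_frame_std"] = std
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(outdir / "events.jsonl", "w") as fh:
        for e in engine.events:
            fh.write(json.dumps(e, sort_keys=True) + "\n")
    return trace
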