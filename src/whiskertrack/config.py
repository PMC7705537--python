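"""YAML run configuration with strict validation.

The file mirrors the module structure; unknown sections or keys are
rejected so typos fail loudly.  Angle thresholds are written in degrees in
the file (``*_deg`` keys) and converted to radians on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from .cluster import ClusterConfig
from .parameterize import FitConfig, SnoutLine
from .pipeline import DetectionConfig
from .preprocess import SilhouetteConfig
from .recognize import RecognizerConfig
from .track import TrackerConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    video: str | None = None
    synthetic_preset: str | None = None
    output_dir: str = "out"
    seed: int = 0
    fps: float = 1000.0
    progress: bool = False
    snout: SnoutLine | None = None
    background_samples: int = 20
    invert: bool = False
    side_margin: float = 8.0
    silhouette: SilhouetteConfig = field(
        default_factory=lambda: SilhouetteConfig(open_radius=3)
    )
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    track: TrackerConfig = field(default_factory=TrackerConfig)
    recognize: RecognizerConfig = field(default_factory=RecognizerConfig)


def _build(cls, section: dict, name: str, deg_keys: dict[str, str] | None = None):
    """Instantiate a config dataclass from a dict, rejecting unknown keys
    and converting ``*_deg`` angles to radians."""
    deg_keys = deg_keys or {}
    allowed = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in section.items():
        if key in deg_keys:
            kwargs[deg_keys[key]] = np.deg2rad(float(value))
        elif key in allowed:
            kwargs[key] = value
        else:
            raise ValueError(f"unknown key {key!r} in section {name!r}")
    return cls(**kwargs)


_SECTIONS = {
    "background": None,  # handled inline (n_samples)
    "silhouette": (SilhouetteConfig, {}),
    "detection": (DetectionConfig, {"min_theta_deg": "min_theta"}),
    "cluster": (ClusterConfig, {"steger_angle_tol_deg": "steger_angle_tol"}),
    "fit": (FitConfig, {}),
    "track": (TrackerConfig, {"max_dtheta_deg": "max_dtheta"}),
    "recognize": (RecognizerConfig, {"min_theta_range_deg": "min_theta_range"}),
}

_TOP_KEYS = {
    "video",
    "synthetic_preset",
    "output_dir",
    "seed",
    "fps",
    "progress",
    "snout",
    "preprocess",
} | set(_SECTIONS)


def config_from_dict(data: dict) -> RunConfig:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = RunConfig()
    for key in ("video", "synthetic_preset", "output_dir", "seed", "fps", "progress"):
        if key in data:
            setattr(cfg, key, data[key])
    if "snout" in data:
        s = dict(data["snout"])
        unknown = set(s) - {"p0", "p1", "flip_normal"}
        if unknown:
            raise ValueError(f"unknown key(s) {sorted(unknown)} in section 'snout'")
        cfg.snout = SnoutLine(
            tuple(map(float, s["p0"])),
            tuple(map(float, s["p1"])),
            bool(s.get("flip_normal", False)),
        )
    if "background" in data:
        b = dict(data["background"])
        unknown = set(b) - {"n_samples"}
        if unknown:
            raise ValueError(
                f"unknown key(s) {sorted(unknown)} in section 'background'"
            )
        cfg.background_samples = int(b.get("n_samples", cfg.background_samples))
    if "preprocess" in data:
        p = dict(data["preprocess"])
        unknown = set(p) - {"invert", "side_margin"}
        if unknown:
            raise ValueError(
                f"unknown key(s) {sorted(unknown)} in section 'preprocess'"
            )
        cfg.invert = bool(p.get("invert", cfg.invert))
        cfg.side_margin = float(p.get("side_margin", cfg.side_margin))
    for name, spec in _SECTIONS.items():
        if name == "background" or name not in data:
            continue
        cls, deg = spec
        setattr(cfg, name if name != "track" else "track",
                _build(cls, dict(data[name]), name, deg))
    if cfg.video and cfg.snout is None:
        raise ValueError("a video run requires a 'snout' section")
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration root must be a mapping")
    return config_from_dict(data)
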