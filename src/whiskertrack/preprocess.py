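"""Pixel-level cleanup: background extraction, subtraction, silhouette removal.

Whiskers are imaged as dark curvilinear structures against a bright backlight.
The static background is estimated as the per-pixel maximum over frames
sampled across the video (anything dark and moving -- whiskers -- drops out of
the maximum).  Subtracting each frame from the background leaves the whiskers
bright on a near-zero background; the snout silhouette and most fur are then
removed with a binarise / morphological-opening / dilation sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.filters import threshold_otsu

from .parameterize import SnoutLine

__all__ = [
    "BackgroundModel",
    "SilhouetteConfig",
    "extract_background",
    "sample_indices",
    "subtract_background",
    "extract_silhouette",
    "remove_silhouette",
    "Preprocessor",
]


@dataclass
class BackgroundModel:
    pixels: np.ndarray  # float, same shape as frames
    sample_indices: list[int]


@dataclass
class SilhouetteConfig:
    threshold: float | None = None  # None -> Otsu on the subtracted image
    open_radius: int = 2  # deletes thin (whisker) structures
    dilate_radius: int = 3  # pads the silhouette
    max_fraction: float = 0.5  # warn if the mask covers more than this


def sample_indices(n_frames: int, n_samples: int = 20) -> list[int]:
    """Evenly spaced frame indices used for background estimation."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames to sample a background")
    n_samples = min(max(n_samples, 2), n_frames)
    return list(np.unique(np.linspace(0, n_frames - 1, n_samples).astype(int)))


def extract_background(
    frames, indices: list[int] | None = None
) -> BackgroundModel:
    """Per-pixel maximum over sampled frames (dark-whisker polarity).

    ``frames`` is either an indexable video (with ``indices`` giving the
    sample positions) or directly an iterable of sampled frames.
    """
    if indices is None:
        sampled = list(frames)
        indices = list(range(len(sampled)))
    else:
        sampled = [frames[i] for i in indices]
    if len(sampled) < 2:
        raise ValueError("background extraction needs at least 2 sampled frames")
    shape = np.asarray(sampled[0]).shape
    bg = np.asarray(sampled[0], float).copy()
    for f in sampled[1:]:
        f = np.asarray(f, float)
        if f.shape != shape:
            raise ValueError("all sampled frames must share one shape")
        np.maximum(bg, f, out=bg)
    return BackgroundModel(pixels=bg, sample_indices=list(indices))


def subtract_background(frame: np.ndarray, bg: BackgroundModel) -> np.ndarray:
    """``clamp(background - frame, 0)``: whiskers become bright on dark."""
    frame = np.asarray(frame, float)
    if frame.shape != bg.pixels.shape:
        raise ValueError("frame and background shapes differ")
    return np.clip(bg.pixels - frame, 0.0, None)


def extract_silhouette(
    image: np.ndarray, cfg: SilhouetteConfig | None = None
) -> np.ndarray:
    """Boolean snout/fur mask from a background-subtracted frame.

    Binarise, delete thin structures (whisker shafts) by morphological
    opening, then pad the remaining blob by dilation.
    """
    cfg = cfg or SilhouetteConfig()
    image = np.asarray(image, float)
    if cfg.threshold is None:
        if np.ptp(image) == 0:
            return np.zeros(image.shape, bool)
        thr = threshold_otsu(image)
    else:
        thr = cfg.threshold
    binary = image > thr
    if not binary.any():
        return binary
    opened = ndi.binary_opening(binary, morphology.disk(cfg.open_radius))
    mask = ndi.binary_dilation(opened, morphology.disk(cfg.dilate_radius))
    frac = mask.mean()
    if frac > cfg.max_fraction:
        warnings.warn(
            f"silhouette mask covers {frac:.0%} of the image; "
            "the binarisation threshold is probably off",
            stacklevel=2,
        )
    return mask


def remove_silhouette(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero the masked pixels, leave the rest unchanged."""
    image = np.asarray(image, float)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    out = image.copy()
    out[mask] = 0.0
    return out


class Preprocessor:
    """Background + silhouette pipeline for a whole video.

    ``fit`` estimates the background from sampled frames; calling the
    instance cleans one frame.  If a snout line is supplied, everything on
    the non-whisker side of the line is zeroed as well (the tracker works on
    one configured side of the snout).
    """

    def __init__(
        self,
        n_samples: int = 20,
        silhouette: SilhouetteConfig | None = None,
        snout: SnoutLine | None = None,
        invert: bool = False,
        side_margin: float = 0.0,
    ):
        self.n_samples = n_samples
        self.silhouette_cfg = silhouette or SilhouetteConfig()
        self.snout = snout
        self.invert = invert
        # pixels closer than side_margin to the line (snout side included)
        # are zeroed; lifts the cut above any residual silhouette-edge band
        self.side_margin = side_margin
        self.background: BackgroundModel | None = None
        self._side_mask: np.ndarray | None = None

    def fit(self, frames) -> "Preprocessor":
        idx = sample_indices(len(frames), self.n_samples)
        sampled = [self._polarity(frames[i]) for i in idx]
        self.background = extract_background(sampled)
        if self.snout is not None:
            h, w = self.background.pixels.shape
            ys, xs = np.mgrid[0:h, 0:w].astype(float)
            nvec = self.snout.normal
            p0 = np.asarray(self.snout.p0, float)
            side = (xs - p0[0]) * nvec[0] + (ys - p0[1]) * nvec[1]
            self._side_mask = side < self.side_margin
        return self

    def _polarity(self, frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame, float)
        if self.invert:
            frame = frame.max() - frame
        return frame

    def __call__(self, frame: np.ndarray) -> np.ndarray:
        if self.background is None:
            raise RuntimeError("call fit() before cleaning frames")
        sub = subtract_background(self._polarity(frame), self.background)
        mask = extract_silhouette(sub, self.silhouette_cfg)
        cleaned = remove_silhouette(sub, mask)
        if self._side_mask is not None:
            cleaned[self._side_mask] = 0.0
        return cleaned
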