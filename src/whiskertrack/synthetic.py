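"""Seeded synthetic whisker videos with exact ground truth.

The generator emulates the imaging situation the tracker is built for: a
bright static backlight with mild texture, a dark snout silhouette whose edge
moves slightly (breathing), fur as short low-contrast ridge fragments near the
snout, and N dark whiskers rendered as Gaussian-profile ridges.  Each whisker
rotates about a fixed hidden pivot behind the snout line, so its ground-truth
(rho, theta) pairs satisfy the pivot relation ``rho = L_f * cot(theta) + rho_f``
exactly, and whisks sinusoidally at a frequency inside the biological 5-30 Hz
band.  Bending is scripted through ``b(t)``; transient bending ramps are the
mechanism for scripted whisker crossings, and occlusion scripts simply skip
rendering a whisker for a frame range.

Frames are rendered lazily and deterministically: frame ``i`` depends only on
the scene config, the seed and ``i``, so random access, re-runs and
sub-sampling all see bit-identical pixels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .parameterize import SnoutLine, WhiskerParams, whisker_curve, _chord_limit

__all__ = [
    "WhiskerSpec",
    "FurConfig",
    "SceneConfig",
    "GroundTruth",
    "SceneFrames",
    "generate_scene",
    "script_occlusion",
    "script_bend",
    "render_curve",
    "render_ridge_image",
    "benchmark_scene",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class WhiskerSpec:
    """One whisker: pivot geometry, whisking kinematics and appearance."""

    rho_f: float  # pivot foot position along the snout line (px)
    L_f: float  # pivot depth behind the snout line (px), > 0
    rest_theta: float  # rad
    amplitude: float  # whisking amplitude (rad)
    freq_hz: float  # whisking frequency (Hz)
    phase: float = 0.0
    length: float = 180.0  # base-to-tip distance (px)
    width_fwhm: float = 3.0  # ridge full width at half maximum (px)
    contrast: float = 150.0  # intensity dip below background
    b0: float = 0.0  # resting bending (px^-1)
    b_amp: float = 0.0  # whisk-locked bending modulation
    b_ramps: tuple[tuple[int, int, float], ...] = ()  # (start, end, delta_b)

    def __post_init__(self) -> None:
        if self.L_f <= 0:
            raise ValueError("pivot depth L_f must be positive")


@dataclass(frozen=True)
class FurConfig:
    n_fragments: int = 40
    max_length: float = 15.0
    band_width: float = 20.0  # distance band above the snout line (px)
    contrast: float = 35.0
    width_fwhm: float = 1.8
    jitter: float = 0.6  # per-frame positional jitter (px)


@dataclass(frozen=True)
class SceneConfig:
    shape: tuple[int, int] = (480, 512)  # (rows, cols)
    fps: float = 1000.0
    n_frames: int = 200
    seed: int = 0
    snout: SnoutLine = field(
        default_factory=lambda: SnoutLine((40.0, 430.0), (470.0, 430.0))
    )
    whiskers: tuple[WhiskerSpec, ...] = ()
    background_level: float = 230.0
    texture_amplitude: float = 6.0
    texture_scale: float = 25.0
    snout_level: float = 35.0
    breath_amplitude: float = 5.0  # px excursion of the silhouette edge
    breath_freq_hz: float = 3.0
    edge_softness: float = 1.5  # px, silhouette edge transition width
    noise_sigma: float = 2.0
    angle_jitter: float = 0.0015  # rad, per-frame white jitter on theta
    fur: FurConfig | None = field(default_factory=FurConfig)
    occlusions: tuple[tuple[int, int, int], ...] = ()  # (whisker, start, stop)

    def __post_init__(self) -> None:
        for w in self.whiskers:
            if not (0.0 < w.freq_hz < self.fps / 2.0):
                raise ValueError("whisking frequency must lie in (0, fps/2)")


def script_occlusion(cfg: SceneConfig, whisker: int, frames: range) -> SceneConfig:
    """Return a config in which ``whisker`` is hidden for the given frames."""
    if len(frames) == 0:
        return cfg
    if frames.start < 0 or frames.stop > cfg.n_frames:
        raise ValueError("occlusion frames outside the video")
    occ = cfg.occlusions + ((whisker, frames.start, frames.stop),)
    return dataclasses.replace(cfg, occlusions=occ)


def script_bend(
    cfg: SceneConfig, whisker: int, frames: range, delta_b: float
) -> SceneConfig:
    """Add a transient raised-cosine bending excursion to one whisker.

    Sweeping a whisker's tip through a neighbour this way is how crossings
    are scripted.
    """
    w = cfg.whiskers[whisker]
    ramps = w.b_ramps + ((frames.start, frames.stop, delta_b),)
    whiskers = list(cfg.whiskers)
    whiskers[whisker] = dataclasses.replace(w, b_ramps=ramps)
    return dataclasses.replace(cfg, whiskers=tuple(whiskers))


# ---------------------------------------------------------------------------
# rendering primitives


def render_curve(
    img: np.ndarray,
    snout: SnoutLine,
    params: WhiskerParams,
    width_fwhm: float,
    contrast: float,
    sign: float = -1.0,
) -> None:
    """Add (or subtract) an antialiased Gaussian-profile ridge in place.

    The profile is evaluated in closed form in the chord frame of the
    quadratic model, so the rendered cross-section is analytically Gaussian
    and the sub-pixel centerline position is exact (no rasterisation).
    """
    sigma = width_fwhm * _FWHM_TO_SIGMA
    pad = 3.5 * sigma + 2.0
    u, n = snout.along, snout.normal
    th, b = params.theta, params.b
    e = np.cos(th) * u + np.sin(th) * n
    m = -np.sin(th) * u + np.cos(th) * n
    base = snout.point_at(params.rho)
    x_max = _chord_limit(b, params.length)
    # bounding box from coarse curve samples
    samples = whisker_curve(params, snout, 32)
    lo = np.floor(samples.min(axis=0) - pad).astype(int)
    hi = np.ceil(samples.max(axis=0) + pad).astype(int)
    h, w = img.shape
    x0, y0 = max(lo[0], 0), max(lo[1], 0)
    x1, y1 = min(hi[0] + 1, w), min(hi[1] + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1, dtype=float)
    ys = np.arange(y0, y1, dtype=float)
    px = xs[None, :] - base[0]
    py = ys[:, None] - base[1]
    cx = px * e[0] + py * e[1]  # chord coordinate
    cd = px * m[0] + py * m[1]  # perpendicular coordinate
    x_eff = np.clip(cx, 0.0, x_max)
    over = cx - x_eff  # beyond the endpoints
    slope = 2.0 * b * x_eff
    g = (cd - b * x_eff * x_eff) / np.sqrt(1.0 + slope * slope)
    dist2 = g * g + over * over
    img[y0:y1, x0:x1] += sign * contrast * np.exp(-dist2 / (2.0 * sigma * sigma))


def _render_segment(
    img: np.ndarray,
    a: np.ndarray,
    bpt: np.ndarray,
    width_fwhm: float,
    contrast: float,
    sign: float = -1.0,
) -> None:
    """Gaussian-profile straight segment from a to bpt (fur fragments)."""
    sigma = width_fwhm * _FWHM_TO_SIGMA
    pad = 3.5 * sigma + 1.0
    lo = np.floor(np.minimum(a, bpt) - pad).astype(int)
    hi = np.ceil(np.maximum(a, bpt) + pad).astype(int)
    h, w = img.shape
    x0, y0 = max(lo[0], 0), max(lo[1], 0)
    x1, y1 = min(hi[0] + 1, w), min(hi[1] + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    d = bpt - a
    L = np.linalg.norm(d)
    if L == 0:
        return
    e = d / L
    xs = np.arange(x0, x1, dtype=float) - a[0]
    ys = np.arange(y0, y1, dtype=float) - a[1]
    cx = xs[None, :] * e[0] + ys[:, None] * e[1]
    cd = -xs[None, :] * e[1] + ys[:, None] * e[0]
    over = cx - np.clip(cx, 0.0, L)
    dist2 = cd * cd + over * over
    img[y0:y1, x0:x1] += sign * contrast * np.exp(-dist2 / (2.0 * sigma * sigma))


def render_ridge_image(
    shape: tuple[int, int],
    point: tuple[float, float],
    angle: float,
    width_fwhm: float,
    contrast: float = 100.0,
    background: float = 0.0,
) -> np.ndarray:
    """Bright infinite straight ridge through ``point`` at ``angle`` (rad).

    Exact closed-form rendering, used as the noiseless localisation fixture:
    every rendered cross-section is a Gaussian of the configured width whose
    analytic crest is the line itself.
    """
    sigma = width_fwhm * _FWHM_TO_SIGMA
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    nx, ny = -np.sin(angle), np.cos(angle)
    d = (xs - point[0]) * nx + (ys - point[1]) * ny
    return background + contrast * np.exp(-d * d / (2.0 * sigma * sigma))


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Per-frame true parameters, visibility and analytic centerlines."""

    params: np.ndarray  # (n_frames, N, 4): rho, theta, b, L
    visible: np.ndarray  # (n_frames, N) bool
    pivots: np.ndarray  # (N, 2): rho_f, L_f
    snout: SnoutLine
    fps: float

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def n_whiskers(self) -> int:
        return self.params.shape[1]

    def whisker_params(self, frame: int, whisker: int) -> WhiskerParams:
        rho, theta, b, length = self.params[frame, whisker]
        return WhiskerParams(rho, theta, b, length, frame_index=frame)

    def centerline(self, frame: int, whisker: int, n_samples: int = 200) -> np.ndarray:
        return whisker_curve(self.whisker_params(frame, whisker), self.snout, n_samples)

    def whisker_support(
        self, frame: int, shape: tuple[int, int], radius: float = 3.0
    ) -> np.ndarray:
        """Boolean mask of pixels within ``radius`` of any visible centerline."""
        h, w = shape
        mask = np.zeros(shape, bool)
        for k in range(self.n_whiskers):
            if not self.visible[frame, k]:
                continue
            pts = self.centerline(frame, k, 400)
            cols = np.round(pts[:, 0]).astype(int)
            rows = np.round(pts[:, 1]).astype(int)
            ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
            mask[rows[ok], cols[ok]] = True
        r = int(np.ceil(radius))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        return ndi.binary_dilation(mask, yy * yy + xx * xx <= radius * radius)

    def crossing_frames(self, i: int, j: int, min_dist: float = 0.75) -> np.ndarray:
        """Frames in which centerlines i and j intersect (approach closer
        than ``min_dist`` px), found by dense sampling of both curves."""
        out = []
        for t in range(self.n_frames):
            if not (self.visible[t, i] and self.visible[t, j]):
                continue
            a = self.centerline(t, i, 150)
            bq = self.centerline(t, j, 150)
            d2 = ((a[:, None, :] - bq[None, :, :]) ** 2).sum(-1)
            if d2.min() < min_dist * min_dist:
                out.append(t)
        return np.asarray(out, int)


# ---------------------------------------------------------------------------
# scene


def _theta_schedule(cfg: SceneConfig) -> np.ndarray:
    """(n_frames, N) whisking angle series, jitter included."""
    t = np.arange(cfg.n_frames) / cfg.fps
    n = len(cfg.whiskers)
    theta = np.empty((cfg.n_frames, n))
    rng = np.random.default_rng([cfg.seed, 7])
    jitter = rng.normal(0.0, cfg.angle_jitter, size=(cfg.n_frames, n))
    for k, wsk in enumerate(cfg.whiskers):
        theta[:, k] = (
            wsk.rest_theta
            + wsk.amplitude * np.sin(2.0 * np.pi * wsk.freq_hz * t + wsk.phase)
            + jitter[:, k]
        )
    return np.clip(theta, 0.05, np.pi - 0.05)


def _b_schedule(cfg: SceneConfig) -> np.ndarray:
    t = np.arange(cfg.n_frames) / cfg.fps
    n = len(cfg.whiskers)
    b = np.empty((cfg.n_frames, n))
    for k, wsk in enumerate(cfg.whiskers):
        b[:, k] = wsk.b0 + wsk.b_amp * np.sin(
            2.0 * np.pi * wsk.freq_hz * t + wsk.phase
        )
        for start, stop, db in wsk.b_ramps:
            fr = np.arange(start, stop)
            ph = (fr - start) / max(stop - start - 1, 1)
            b[fr, k] += db * 0.5 * (1.0 - np.cos(2.0 * np.pi * ph))
    return b


def _ground_truth(cfg: SceneConfig) -> GroundTruth:
    theta = _theta_schedule(cfg)
    b = _b_schedule(cfg)
    n = len(cfg.whiskers)
    params = np.empty((cfg.n_frames, n, 4))
    for k, wsk in enumerate(cfg.whiskers):
        cot = 1.0 / np.tan(theta[:, k])
        params[:, k, 0] = wsk.rho_f + wsk.L_f * cot
        params[:, k, 1] = theta[:, k]
        params[:, k, 2] = b[:, k]
        params[:, k, 3] = wsk.length
    visible = np.ones((cfg.n_frames, n), bool)
    for w, start, stop in cfg.occlusions:
        visible[start:stop, w] = False
    pivots = np.array([[w.rho_f, w.L_f] for w in cfg.whiskers]).reshape(n, 2)
    return GroundTruth(params, visible, pivots, cfg.snout, cfg.fps)


class SceneFrames:
    """Lazy, randomly accessible frame sequence (uint8)."""

    def __init__(self, cfg: SceneConfig, truth: GroundTruth):
        self.cfg = cfg
        self.truth = truth
        self.shape = cfg.shape
        self.fps = cfg.fps
        h, w = cfg.shape
        static_rng = np.random.default_rng([cfg.seed, 11])
        texture = ndi.gaussian_filter(
            static_rng.normal(size=cfg.shape), cfg.texture_scale
        )
        if texture.std() > 0:
            texture *= cfg.texture_amplitude / texture.std()
        self._background = cfg.background_level + texture
        ys, xs = np.mgrid[0:h, 0:w].astype(float)
        nvec = cfg.snout.normal
        p0 = np.asarray(cfg.snout.p0, float)
        self._snout_dist = (xs - p0[0]) * nvec[0] + (ys - p0[1]) * nvec[1]
        self._fur = self._make_fur(static_rng)

    def _make_fur(self, rng: np.random.Generator):
        fur = self.cfg.fur
        if fur is None or fur.n_fragments == 0:
            return []
        snout = self.cfg.snout
        p0 = np.asarray(snout.p0, float)
        span = float(np.linalg.norm(np.asarray(snout.p1) - p0))
        frags = []
        for _ in range(fur.n_fragments):
            rho = rng.uniform(0.0, span)
            dist = rng.uniform(0.0, fur.band_width)
            a = snout.point_at(rho) + dist * snout.normal
            ang = rng.uniform(0.0, np.pi)
            ln = rng.uniform(4.0, fur.max_length)
            d = np.array([np.cos(ang), np.sin(ang)])
            frags.append((a, a + ln * d))
        return frags

    def __len__(self) -> int:
        return self.cfg.n_frames

    def background_image(self) -> np.ndarray:
        """The generator's static backlight (no snout, whiskers or noise)."""
        return self._background.copy()

    def render_float(self, i: int, noise: bool = True) -> np.ndarray:
        cfg = self.cfg
        if not 0 <= i < cfg.n_frames:
            raise IndexError(i)
        img = self._background.copy()
        # whiskers (drawn before the silhouette so proximal parts are hidden)
        for k, wsk in enumerate(cfg.whiskers):
            if not self.truth.visible[i, k]:
                continue
            render_curve(
                img,
                cfg.snout,
                self.truth.whisker_params(i, k),
                wsk.width_fwhm,
                wsk.contrast,
            )
        # fur with small per-frame jitter
        if self._fur:
            rng = np.random.default_rng([cfg.seed, 13, i])
            offs = rng.normal(0.0, cfg.fur.jitter, size=(len(self._fur), 2))
            for (a, bpt), off in zip(self._fur, offs):
                _render_segment(
                    img, a + off, bpt + off, cfg.fur.width_fwhm, cfg.fur.contrast
                )
        # breathing snout silhouette
        t = i / cfg.fps
        delta = cfg.breath_amplitude * np.sin(2.0 * np.pi * cfg.breath_freq_hz * t)
        edge = 1.0 / (1.0 + np.exp(-(self._snout_dist - delta) / cfg.edge_softness))
        img = cfg.snout_level + (img - cfg.snout_level) * edge
        if noise and cfg.noise_sigma > 0:
            rng = np.random.default_rng([cfg.seed, 17, i])
            img += rng.normal(0.0, cfg.noise_sigma, size=cfg.shape)
        return img

    def __getitem__(self, i: int) -> np.ndarray:
        return np.clip(np.round(self.render_float(i)), 0, 255).astype(np.uint8)

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def write_tiff(self, path) -> None:
        import tifffile

        with tifffile.TiffWriter(str(path)) as tw:
            for frame in self:
                tw.write(frame, contiguous=True)


def generate_scene(cfg: SceneConfig) -> tuple[SceneFrames, GroundTruth]:
    """Build the lazy frame sequence and its exact ground truth."""
    truth = _ground_truth(cfg)
    return SceneFrames(cfg, truth), truth


# ---------------------------------------------------------------------------
# presets


def benchmark_scene(
    n_frames: int = 2000, seed: int = 42, n_whiskers: int = 10
) -> SceneConfig:
    """The default tracking benchmark: 10 whiskers on a 480x512 frame at a
    1 kHz-equivalent rate, whisking in near-phase at 8 Hz, with two scripted
    tip crossings and one 20-frame occlusion."""
    whiskers = []
    for i in range(n_whiskers):
        whiskers.append(
            WhiskerSpec(
                rho_f=60.0 + 38.0 * i,
                L_f=35.0 + 2.0 * i,
                rest_theta=np.deg2rad(65.0 + 6.0 * i),
                amplitude=0.30,
                freq_hz=8.0,
                phase=0.04 * (i - n_whiskers / 2),
                length=140.0 + 7.0 * i,
                width_fwhm=2.4 + 0.12 * i,
                contrast=120.0 + 8.0 * i,
                b0=-8e-5 * (i - (n_whiskers - 1) / 2),
                b_amp=1.5e-4,
            )
        )
    cfg = SceneConfig(
        shape=(480, 512),
        fps=1000.0,
        n_frames=n_frames,
        seed=seed,
        snout=SnoutLine((20.0, 430.0), (500.0, 430.0)),
        whiskers=tuple(whiskers),
    )
    if n_whiskers >= 5 and n_frames >= 700:
        # two transient bending excursions sweep whisker tips across their
        # neighbours -> scripted crossings
        cfg = script_bend(cfg, 3, range(480, 560), 1.3e-3)
        cfg = script_bend(cfg, 6, range(n_frames - 700, n_frames - 620), -1.3e-3)
    if n_whiskers >= 8 and n_frames >= 1100:
        cfg = script_occlusion(cfg, 7, range(1000, 1020))
    return cfg
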