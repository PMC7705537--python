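import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from whiskertrack.parameterize import SnoutLine
from whiskertrack.synthetic import (
    FurConfig,
    SceneConfig,
    WhiskerSpec,
    generate_scene,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_scene_config(
    n_whiskers: int = 4,
    n_frames: int = 100,
    seed: int = 1,
    amplitude: float = 0.25,
    fur: FurConfig | None = None,
    **overrides,
) -> SceneConfig:
    """A compact 256x320 scene with well-separated whiskers (no crossings)."""
    whiskers = tuple(
        WhiskerSpec(
            rho_f=40.0 + 60.0 * i,
            L_f=30.0 + 3.0 * i,
            rest_theta=np.deg2rad(70.0 + 10.0 * i),
            amplitude=amplitude,
            freq_hz=8.0,
            phase=0.05 * i,
            length=90.0 + 8.0 * i,
            width_fwhm=2.5 + 0.1 * i,
            contrast=130.0 + 10.0 * i,
            b0=5e-5 * (i - (n_whiskers - 1) / 2),
            b_amp=1e-4,
        )
        for i in range(n_whiskers)
    )
    defaults = dict(
        shape=(256, 320),
        fps=1000.0,
        n_frames=n_frames,
        seed=seed,
        snout=SnoutLine((10.0, 210.0), (310.0, 210.0)),
        whiskers=whiskers,
        fur=fur,
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)


@pytest.fixture(scope="session")
def small_scene():
    """(frames, truth, cfg) for a 4-whisker, 100-frame scene without fur."""
    cfg = small_scene_config()
    frames, truth = generate_scene(cfg)
    return frames, truth, cfg


@pytest.fixture(scope="session")
def furry_scene():
    """Same geometry with fur fragments near the snout."""
    cfg = small_scene_config(seed=2, fur=FurConfig(n_fragments=25))
    frames, truth = generate_scene(cfg)
    return frames, truth, cfg
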