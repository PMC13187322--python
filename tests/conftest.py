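import numpy as np
import pytest

from memtopo import PipelineConfig
from memtopo.synthetic import (
    SyntheticSceneParams,
    TargetSpec,
    generate_scene,
    photon_scale_for_snr,
    suggested_config,
)


def annulus_image(size=256, radius=71.0, thickness=3.0, amplitude=100.0):
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - size / 2, xx - size / 2)
    img = np.where((r >= radius) & (r < radius + thickness), amplitude, 0.0)
    disc = r < radius
    return img, disc


def small_scene_params(**kw):
    """Compact default scene used across tests (fast, SNR 10)."""
    defaults = dict(
        field_size_px=256,
        body_radius_px=45.0,
        n_protrusions=6,
        protrusion_length_px=(12.0, 20.0),
        n_frames=1,
        seed=0,
        photon_scale=photon_scale_for_snr(10.0, 100.0),
    )
    defaults.update(kw)
    return SyntheticSceneParams(**defaults)


@pytest.fixture(scope="session")
def resting_scene():
    params = small_scene_params(seed=3)
    scene, stack = generate_scene(params)
    return params, scene, stack


@pytest.fixture(scope="session")
def contact_scene():
    params = small_scene_params(
        seed=4, n_frames=6, target=TargetSpec(onset_frame=2)
    )
    scene, stack = generate_scene(params)
    return params, scene, stack


@pytest.fixture()
def scene_cfg():
    def make(params, **overrides) -> PipelineConfig:
        return suggested_config(params, **overrides)

    return make
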