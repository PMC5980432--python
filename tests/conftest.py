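import numpy as np
import pytest

from iseikit.synth import CurveSpec, SceneSpec, make_curve, rasterize_scene

HELIX_PARAMS = {"radius": 0.01, "pitch": 0.003, "turns": 4.5}


@pytest.fixture(scope="session")
def helix_curve():
    return make_curve(CurveSpec("helix", HELIX_PARAMS), n_samples=400)


@pytest.fixture(scope="session")
def helix_scene(helix_curve):
    """Rasterized helix egg at the standard anisotropic spacing."""
    scene = SceneSpec(seed=11)
    grid, masks, gt = rasterize_scene(scene, helix_curve.points,
                                      helix_curve.descriptors)
    return grid, masks, gt


@pytest.fixture(scope="session")
def fig8_curve():
    spec = CurveSpec("figure8", {"lobe_radius": 0.03, "axial_offset": 0.0015})
    return make_curve(spec, n_samples=400)


@pytest.fixture(scope="session")
def fig8_scene(fig8_curve):
    scene = SceneSpec(seed=12)
    grid, masks, gt = rasterize_scene(scene, fig8_curve.points,
                                      fig8_curve.descriptors)
    return grid, masks, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
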