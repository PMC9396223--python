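import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def easy_pairs():
    """Six small occlusion-free scenes with well-spaced fruits."""
    from litchidet.synthetic import easy_spec, generate_scene

    return [generate_scene(easy_spec(width=192, height=192, n_fruits=5,
                                     radius=(14, 20), seed=s))
            for s in range(6)]


@pytest.fixture(scope="session")
def cluster_scene():
    """One denser scene with occluders, for geometry/IO tests."""
    from litchidet.synthetic import SceneSpec, generate_scene

    return generate_scene(SceneSpec(width=256, height=256,
                                    n_fruits_range=(20, 30), seed=99))


@pytest.fixture()
def voc_corpus(tmp_path):
    """A tiny on-disk VOC corpus."""
    from litchidet.synthetic import SceneSpec, generate_dataset

    spec = SceneSpec(width=96, height=96, n_fruits_range=(4, 9),
                     fruit_radius_range=(5, 9))
    records = generate_dataset(8, tmp_path / "voc", spec, seed=5)
    return tmp_path / "voc", records
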