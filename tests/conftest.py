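import numpy as np
import pytest

from cytoquant import synthkit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ensemble():
    """20 cells, one event each, no bleaching, mild noise."""
    spec = synthkit.SyntheticTraceSpec(
        n_cells=20, n_frames=80, events_per_cell=1, seed=7,
        magnitude_bounds=(2.0, 20.0), noise_sd=0.1,
    )
    return synthkit.gen_trace_ensemble(spec)


@pytest.fixture(scope="session")
def small_scene():
    spec = synthkit.SyntheticTraceSpec(
        n_cells=4, n_frames=25, events_per_cell=1, seed=3,
        magnitude_bounds=(5.0, 40.0), noise_sd=0.0,
    )
    table, truth = synthkit.gen_trace_ensemble(spec)
    scene = synthkit.SyntheticSceneSpec(image_shape=(160, 160), n_lipoplexes=5)
    images, itruth = synthkit.gen_image_sequence(scene, truth, seed=3)
    return scene, images, itruth, truth
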