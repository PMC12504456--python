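import numpy as np
import pytest

from coinvade import synthgen


@pytest.fixture(scope="session")
def small_config() -> synthgen.SceneConfig:
    """A 360-m scene: every grid family still nests, but generation is fast."""
    return synthgen.SceneConfig(
        extent=360.0, kernel_width=15.0, n_dates_landsat=5,
        n_plots=160, rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_scene(small_config) -> synthgen.Scene:
    return synthgen.make_scene(small_config)


@pytest.fixture(scope="session")
def small_layers(small_scene) -> dict:
    from coinvade import pipeline

    return pipeline.rs_feature_layers(small_scene)
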