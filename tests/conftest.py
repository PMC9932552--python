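import numpy as np
import pytest

from headingflow.flow import SceneConfig
from headingflow.model import build_templates


@pytest.fixture(scope="session")
def scene():
    return SceneConfig()


@pytest.fixture(scope="session")
def bank(scene):
    """Default 128-template bank, shared across tests (expensive to build)."""
    return build_templates(scene.resolution, scene)


@pytest.fixture(scope="session")
def small_scene():
    """Reduced geometry for cheap model-level tests."""
    return SceneConfig(n_dots=2000, resolution=32)


@pytest.fixture(scope="session")
def small_bank(small_scene):
    return build_templates(small_scene.resolution, small_scene)
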