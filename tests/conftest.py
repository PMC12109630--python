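import numpy as np
import pytest

from glandcell.patching import build_biopsy_container
from glandcell.synthetic import SceneSpec, render_scene


@pytest.fixture(scope="session")
def standard_scene():
    """One deterministic mid-size synthetic biopsy scene."""
    return render_scene(SceneSpec(seed=42))


@pytest.fixture(scope="session")
def scene_container(standard_scene):
    """64-px container cut from the standard scene, truth labels attached."""
    sc = standard_scene
    cont = build_biopsy_container(sc.image, sc.nuclei, sc.glands, 64, biopsy_id="fixture")
    for rec in cont.records:
        rec.label = sc.labels[rec.nucleus_id]
    return cont


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
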