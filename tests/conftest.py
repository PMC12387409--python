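import numpy as np
import pytest

import placido_edge as pe


@pytest.fixture(scope="session")
def circle_spec():
    return pe.CircleSpec()


@pytest.fixture(scope="session")
def circle_image(circle_spec):
    return pe.make_binary_circle(circle_spec)


@pytest.fixture(scope="session")
def circle_detection(circle_image):
    """Full-pipeline result on the standard circle benchmark (run once)."""
    return pe.detect_subpixel_edges(circle_image, keep_intermediates=True)


@pytest.fixture(scope="session")
def masks9():
    return pe.build_masks(9, 64)


@pytest.fixture(scope="session")
def phantom():
    spec = pe.PhantomSpec(seed=1)
    img, truth = pe.make_placido_phantom(spec)
    return spec, img, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
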