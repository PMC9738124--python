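import numpy as np
import pytest

from pygleason import SlideImage, SyntheticSpec, make_label_map, make_slide


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(width=320, height=320, n_regions=40, seed=11)


@pytest.fixture(scope="session")
def small_slide(small_spec) -> SlideImage:
    return make_slide(small_spec)


@pytest.fixture(scope="session")
def small_label_map(small_slide) -> np.ndarray:
    return small_slide.label_map


@pytest.fixture(scope="session")
def medium_slide() -> SlideImage:
    # large enough for the default 100-px level
    return make_slide(SyntheticSpec(width=420, height=420, n_regions=60, seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
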