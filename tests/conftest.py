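import numpy as np
import pytest

from fetdyn.core import DynamicImage, FrameSchedule, ImageGeometry


@pytest.fixture
def schedule() -> FrameSchedule:
    return FrameSchedule.standard()


@pytest.fixture
def small_geometry() -> ImageGeometry:
    return ImageGeometry((8, 10, 12), (2.0, 2.0, 2.0))


@pytest.fixture
def uniform_image(schedule, small_geometry) -> DynamicImage:
    """Spatially uniform frames valued 1..8."""
    values = np.ones((schedule.n_frames,) + small_geometry.shape)
    values *= np.arange(1, 9)[:, None, None, None]
    return DynamicImage(small_geometry, schedule, values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
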