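import numpy as np
import pytest

from neurotrace.image_io import ImageGrid, ScaleInfo


@pytest.fixture
def scale() -> ScaleInfo:
    return ScaleInfo(0.625)


@pytest.fixture
def paper_scale() -> ScaleInfo:
    return ScaleInfo(0.3125)


def uniform_image(value: float, shape=(64, 64), scale=ScaleInfo(0.625)) -> ImageGrid:
    """An already-normalized constant image (bypasses min-max mapping)."""
    return ImageGrid(np.full(shape, value), scale)


def ridge_image(
    shape=(128, 256),
    row: float = 64.0,
    intensity: float = 1.0,
    sigma_px: float = 1.7,
    scale=ScaleInfo(0.625),
) -> ImageGrid:
    """A horizontal Gaussian-profile ridge on a floor background."""
    rr = np.arange(shape[0], dtype=float)
    profile = intensity * np.exp(-((rr - row) ** 2) / (2 * sigma_px**2))
    arr = np.clip(np.tile(profile[:, None], (1, shape[1])), 1e-6, 1.0)
    return ImageGrid(arr, scale)


def circle_boundary(center, radius_px: float, n: int = 720) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius_px * np.sin(th), center[1] + radius_px * np.cos(th)]
    )
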