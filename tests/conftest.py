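import numpy as np
import pytest

from fcslat.grid import BinaryMask, Bold4D, ImageGrid


@pytest.fixture
def grid443():
    return ImageGrid((4, 4, 2))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_bold(grid: ImageGrid, values: np.ndarray, tr: float = 3.0) -> Bold4D:
    return Bold4D(grid, values, tr_seconds=tr)


@pytest.fixture
def full_mask_grid():
    """A (10, 10, 3) grid with an all-true mask: 300 network voxels."""
    grid = ImageGrid((10, 10, 3))
    return grid, BinaryMask(grid, np.ones(grid.dims, dtype=bool))
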