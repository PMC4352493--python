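import numpy as np
import pytest

from rppd import PlantedRegion, generate_binary_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_region_mask():
    """Three well-separated solid 300x300 planted squares with faint scatter."""
    regions = [
        PlantedRegion(40, 40, 300, 300, 1.0),
        PlantedRegion(40, 460, 300, 300, 1.0),
        PlantedRegion(440, 150, 300, 300, 1.0),
    ]
    mask, truth = generate_binary_fixture(
        (800, 820), regions, scatter_fraction=0.002, rng=np.random.default_rng(7)
    )
    return mask, truth


def overlaps(extent, region: PlantedRegion) -> bool:
    """Half-open extent intersects the planted region's extent."""
    t, l, b, r = extent
    return not (b <= region.top or region.bottom <= t or r <= region.left or region.right <= l)
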