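import numpy as np
import pytest

from mangrove_health.raster_io import CategoricalRaster, Legend


@pytest.fixture
def legend2():
    """Two classes: mangrove (1) and water/other (2)."""
    return Legend(entries=((1, "mangrove", True), (2, "other", False)), nodata_code=0)


@pytest.fixture
def legend6():
    """Ca Mau-style legend: four mangrove types + aquaculture + settlement."""
    return Legend(
        entries=(
            (1, "Rnmd", True),
            (2, "Rnmm", True),
            (3, "Rnmhgdm", True),
            (4, "Rnmhgmd", True),
            (5, "Ntts", False),
            (6, "Dt", False),
        ),
        nodata_code=0,
    )


@pytest.fixture
def make_raster(legend6):
    """Factory for random small categorical rasters (optionally with nodata)."""

    def _make(shape=(12, 12), seed=0, n_classes=4, nodata_frac=0.0, pixel=1.5):
        rng = np.random.default_rng(seed)
        grid = rng.integers(1, n_classes + 1, size=shape).astype(np.int32)
        if nodata_frac > 0:
            grid[rng.random(shape) < nodata_frac] = 0
        return CategoricalRaster(grid=grid, pixel_size_m=pixel, legend=legend6)

    return _make
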