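import numpy as np
import pytest

from memloc import CellGeometry, CompartmentParams


def chebyshev_ring_oracle(mask: np.ndarray, width: int) -> np.ndarray:
    """Brute-force ring definition, independent of the erosion implementation:
    a mask pixel is in the ring iff its minimum Chebyshev distance to any
    exterior pixel (out-of-image counts as exterior) is <= width."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    exterior = np.argwhere(~padded)
    ring = np.zeros_like(mask)
    for (r, c) in np.argwhere(padded):
        d = np.abs(exterior - (r, c)).max(axis=1).min()
        if d <= width:
            ring[r - 1, c - 1] = True
    return ring


@pytest.fixture
def default_params():
    """Compartment parameters used throughout simulator-driven tests:
    4 px ring, threshold 0.7, known constant background subtracted."""
    return CompartmentParams(ring_width_px=4, threshold=0.7,
                             background_mode="constant",
                             background_value=100.0)


@pytest.fixture
def default_geometry():
    return CellGeometry("g0", center=(40.0, 40.0), length_px=45.0,
                        width_px=15.0, orientation_rad=0.3, mode="cytosolic")


def random_mask(rng: np.random.Generator, size: int = 16) -> np.ndarray:
    """Random small blob mask (union of a few rectangles), possibly ragged."""
    m = np.zeros((size, size), dtype=bool)
    for _ in range(rng.integers(1, 4)):
        r0, c0 = rng.integers(0, size - 3, size=2)
        h, w = rng.integers(2, size // 2, size=2)
        m[r0:r0 + h, c0:c0 + w] = True
    return m
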