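import numpy as np
import pytest

from mapaniso import VolumeGrid, OrientationGrid


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def noise_volume(rng):
    """32³ white-noise map at 1 Å/voxel."""
    return VolumeGrid(rng.normal(size=(32, 32, 32)), 1.0)


@pytest.fixture
def coarse_grid():
    """15° orientation grid: fast and still dense enough for argmax checks."""
    return OrientationGrid.regular(np.pi / 12, np.pi / 12)


def trilinear_wrap(volume, pts_idx):
    """Reference trilinear interpolation with periodic wrap.

    Independent of scipy's map_coordinates: explicit 8-corner weighting at
    fractional index coordinates ``pts_idx`` (rows of [z, y, x]).
    """
    n = volume.shape[0]
    base = np.floor(pts_idx).astype(int)
    frac = pts_idx - base
    out = np.zeros(len(pts_idx))
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = (
                    (frac[:, 0] if dz else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dx else 1 - frac[:, 2])
                )
                out += w * volume[
                    (base[:, 0] + dz) % n,
                    (base[:, 1] + dy) % n,
                    (base[:, 2] + dx) % n,
                ]
    return out
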