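"""Reading and writing cryo-EM density maps in MRC/CCP4 format.

Maps are held as :class:`VolumeGrid`: a cubic voxel grid with a single
physical voxel size (Å) and an origin offset.  Internally the data array is
indexed ``[z, y, x]`` (slowest axis = z), matching the standard MRC section
ordering; files whose header permutes the axes are normalized on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = ["VolumeGrid", "read_map", "write_map"]

#: header words (1-based) holding the MRC2014 ORIGIN record
_ORIGIN_WORDS = (50, 51, 52)


@dataclass
class VolumeGrid:
    """A cubic real-space scalar field with physical metadata.

    Parameters
    ----------
    data:
        ``(N, N, N)`` float array indexed ``[z, y, x]``.
    voxel_size:
        Edge length of one voxel in Å (identical on all axes).
    origin:
        Physical offset of the first voxel in Å.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"non-cubic grid: shape {self.data.shape}")
        if self.data.shape[0] < 8:
            raise ValueError(f"grid too small: N={self.data.shape[0]} < 8")
        self.voxel_size = float(self.voxel_size)
        if not self.voxel_size > 0:
            raise ValueError(f"voxel size must be positive, got {self.voxel_size}")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite values in volume data")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def n(self) -> int:
        """Grid side length in voxels."""
        return self.data.shape[0]

    @property
    def nyquist_resolution(self) -> float:
        """Finest representable resolution, 2 × voxel size, in Å."""
        return 2.0 * self.voxel_size

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.voxel_size, self.origin.copy())


def read_map(path: str | os.PathLike) -> VolumeGrid:
    """Read an MRC/CCP4 volume into a :class:`VolumeGrid`.

    Integer-mode maps are promoted to 32-bit float.  Files whose
    MAPC/MAPR/MAPS header permutes the axis order are reordered so that the
    returned array is indexed ``[z, y, x]``.  Non-cubic grids and
    anisotropic voxel sizes are rejected because orientation angles would be
    ambiguous on such grids.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        ccp4 = gemmi.read_ccp4_map(path)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"corrupt or unreadable MRC file {path!r}: {exc}") from exc
    ccp4.setup(0.0, gemmi.MapSetup.ReorderOnly)
    arr = np.array(ccp4.grid, copy=True)  # gemmi index order is [x, y, z]
    if len(set(arr.shape)) != 1:
        raise ValueError(f"non-cubic grid in {path!r}: shape {arr.shape[::-1]}")
    spacing = np.asarray(ccp4.grid.spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError(f"zero or negative voxel size in {path!r}: {spacing}")
    if not np.allclose(spacing, spacing[0], rtol=1e-4):
        raise ValueError(f"anisotropic voxel size in {path!r}: {spacing}")
    origin = np.array([ccp4.header_float(w) for w in _ORIGIN_WORDS])
    return VolumeGrid(arr.T.astype(np.float32), float(spacing[0]), origin)


def write_map(volume: VolumeGrid, path: str | os.PathLike) -> None:
    """Write a :class:`VolumeGrid` as a standard mode-2 (float32) MRC file."""
    if not np.isfinite(volume.data).all():
        raise ValueError("non-finite values in volume data")
    n = volume.n
    grid = gemmi.FloatGrid(np.ascontiguousarray(volume.data.T, dtype=np.float32))
    extent = n * volume.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(extent, extent, extent, 90.0, 90.0, 90.0))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip(_ORIGIN_WORDS, volume.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(os.fspath(path))
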