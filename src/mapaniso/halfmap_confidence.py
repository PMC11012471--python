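"""Half-map Fourier confidence: normalized differences between half maps.

For independently refined half maps with Fourier transforms V1 and V2 the
map normalized difference

    MD(k) = |V1(k) - V2(k)| / (|V1(k)| + |V2(k)|)

is a per-frequency confidence reading: where the halves agree (high SSNR)
MD is near 0, where they are dominated by independent noise MD approaches
its noise expectation, and antiphase coefficients give the upper bound 1.
Central Fourier-plane amplitude slices are provided alongside to visualize
directional SSNR structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier_geometry import forward_fft
from .volume_io import VolumeGrid

__all__ = [
    "ConfidenceMap",
    "confidence_map",
    "axis_plane_slices",
    "resolution_ring_radius",
]

# relative amplitude below which both halves are treated as empty (MD := 1)
_DENOMINATOR_GUARD = 1e-12


@dataclass
class ConfidenceMap:
    """MD values on the DC-centered frequency grid, in [0, 1]."""

    md: np.ndarray
    voxel_size: float

    @property
    def n(self) -> int:
        return self.md.shape[0]


def confidence_map(half1: VolumeGrid, half2: VolumeGrid) -> ConfidenceMap:
    """Voxel-wise MD between two half maps.

    Where the combined amplitude |V1|+|V2| falls below ``1e-12`` of the
    grid's maximum amplitude, MD is set to 1: no signal means no
    confidence.  The result is centrosymmetric for real half maps and
    invariant under a common global rescaling of both inputs.
    """
    if half1.data.shape != half2.data.shape:
        raise ValueError(
            f"grid mismatch: {half1.data.shape} vs {half2.data.shape}"
        )
    if not np.isclose(half1.voxel_size, half2.voxel_size, rtol=1e-6):
        raise ValueError(
            f"voxel size mismatch: {half1.voxel_size} vs {half2.voxel_size}"
        )
    v1 = forward_fft(half1).coefficients
    v2 = forward_fft(half2).coefficients
    num = np.abs(v1 - v2)
    den = np.abs(v1) + np.abs(v2)
    amp_max = float(den.max())
    guard = _DENOMINATOR_GUARD * amp_max
    with np.errstate(invalid="ignore", divide="ignore"):
        md = np.where(den > guard, num / np.where(den > 0, den, 1.0), 1.0)
    return ConfidenceMap(np.clip(md, 0.0, 1.0), half1.voxel_size)


def axis_plane_slices(field: np.ndarray) -> dict[str, np.ndarray]:
    """Central planes of a DC-centered 3D field through the DC voxel.

    Returns the z=0, y=0 and x=0 planes (keys ``"z=0"`` etc.), each a 2D
    array.  The field is indexed ``[z, y, x]`` with DC at ``N//2``.
    """
    if field.ndim != 3:
        raise ValueError("expected a 3D field")
    c = field.shape[0] // 2
    return {"z=0": field[c, :, :], "y=0": field[:, c, :], "x=0": field[:, :, c]}


def resolution_ring_radius(n: int, voxel_size: float, resolution: float) -> float:
    """Radius in pixels (from the plane center) of a resolution circle.

    A feature at ``resolution`` Å sits at frequency ``1/resolution`` 1/Å,
    i.e. ``n·voxel_size/resolution`` frequency-grid pixels from DC.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return n * voxel_size / resolution
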