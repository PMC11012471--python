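"""Soft masks: the inverted spherical solvent mask and reference-derived masks.

The solvent mask is the heart of the noise-anisotropy method: it zeroes the
box center where the macromolecule sits and keeps the surrounding solvent
shell, so only reconstruction noise enters the directional power analysis.
Reference-derived masks serve the opposite purpose, isolating the particle
for FSC computations.  Both use a raised-cosine (half-cosine) edge profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import VolumeGrid

__all__ = ["SoftMask", "spherical_solvent_mask", "reference_mask", "apply_mask"]

DEFAULT_EDGE_VOXELS = 5.0
DEFAULT_RADIUS_FRACTION = 0.4  # solvent-mask radius as a fraction of the box side


@dataclass
class SoftMask:
    """Voxel weights in [0, 1] plus the geometry they were built from."""

    weights: np.ndarray
    kind: str  # "solvent-spherical" or "reference-derived"
    radius: float | None = None  # voxels (solvent) ...
    threshold: float | None = None  # ... or density threshold (reference)
    edge: float = 0.0  # soft-edge width in voxels

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.min() < -1e-9 or w.max() > 1 + 1e-9:
            raise ValueError("mask weights must lie in [0, 1]")
        self.weights = np.clip(w, 0.0, 1.0)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def _center_distances(n: int) -> np.ndarray:
    """Distance of each voxel from the geometric box center, in voxels."""
    ax = np.arange(n) - (n - 1) / 2.0
    return np.sqrt(
        ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    )


def _raised_cosine_step(r: np.ndarray, r0: float, width: float) -> np.ndarray:
    """0 for r ≤ r0, 1 for r ≥ r0+width, half-cosine ramp between."""
    if width <= 0:
        return (r > r0).astype(np.float64)
    t = np.clip((r - r0) / width, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * t))


def spherical_solvent_mask(
    n: int,
    radius: float | None = None,
    edge: float = DEFAULT_EDGE_VOXELS,
) -> SoftMask:
    """Inverted spherical soft mask: 0 at the box center, 1 in the corners.

    ``radius`` is the outer radius (voxels) at which the weight reaches 1;
    the weight is exactly 0 inside ``radius - edge`` and follows a
    raised-cosine ramp across the edge (0.5 at ``radius - edge/2``).
    Defaults: radius = 0.4·N, edge = 5 voxels.
    """
    if radius is None:
        radius = DEFAULT_RADIUS_FRACTION * n
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if edge < 0:
        raise ValueError(f"edge must be non-negative, got {edge}")
    if radius >= n * np.sqrt(3) / 2:
        raise ValueError(
            f"radius {radius} leaves no solvent in a box of side {n} "
            f"(corner distance {n * np.sqrt(3) / 2:.1f})"
        )
    if radius + edge > n / 2:
        warnings.warn(
            f"solvent shell is very thin: radius+edge = {radius + edge} "
            f"exceeds half the box side ({n / 2})",
            stacklevel=2,
        )
    r = _center_distances(n)
    weights = _raised_cosine_step(r, radius - edge, edge)
    return SoftMask(weights, "solvent-spherical", radius=float(radius), edge=float(edge))


def reference_mask(
    reference: VolumeGrid, threshold: float = 0.01, edge: float = DEFAULT_EDGE_VOXELS
) -> SoftMask:
    """Soft mask around a reference density, for FSC masking.

    The reference is binarized at ``threshold`` and a raised-cosine shell of
    ``edge`` voxels is added outside the binary region (weight 1 inside,
    falling to 0 over the edge width, measured by Euclidean distance to the
    region).
    """
    data = reference.data
    binary = data >= threshold
    if not binary.any():
        raise ValueError(f"empty mask: no voxels at or above threshold {threshold}")
    if edge < 0:
        raise ValueError(f"edge must be non-negative, got {edge}")
    if edge == 0:
        weights = binary.astype(np.float64)
    else:
        dist = ndimage.distance_transform_edt(~binary)
        weights = 1.0 - _raised_cosine_step(dist, 0.0, edge)
        weights[binary] = 1.0
    return SoftMask(
        weights, "reference-derived", threshold=float(threshold), edge=float(edge)
    )


def apply_mask(volume: VolumeGrid, mask: SoftMask) -> VolumeGrid:
    """Voxel-wise product of map and mask; metadata is preserved."""
    if volume.data.shape != mask.weights.shape:
        raise ValueError(
            f"grid mismatch: map {volume.data.shape} vs mask {mask.weights.shape}"
        )
    return VolumeGrid(
        volume.data * mask.weights, volume.voxel_size, volume.origin.copy()
    )
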