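"""Synthetic maps: Gaussian phantoms, isotropic noise, and noise with
preferred-orientation structure.

The generator embodies the forward rationale behind the solvent-noise
estimator.  In a gridding-based single-particle reconstruction, the map's
Fourier value along a direction is a weighted average over the particles
whose central slices pass near that direction; averaging N independent
noise contributions shrinks the residual noise variance like 1/N.  A
non-uniform view distribution therefore leaves a directional imprint on
the noise power: directions covered by few particle slices stay noisy.
``apply_preferred_orientation_noise`` injects exactly this structure —
Fourier-domain Gaussian noise with standard deviation ∝ 1/sqrt(C(k̂)),
where C(k̂) aggregates the effective particle counts of all orientations
whose central plane passes within a small tolerance of direction k̂ —
without running an actual reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fourier_geometry import OrientationGrid
from .masking import DEFAULT_EDGE_VOXELS, DEFAULT_RADIUS_FRACTION
from .volume_io import VolumeGrid

__all__ = [
    "PhantomSpec",
    "OrientationDistribution",
    "gaussian_phantom",
    "globular_spec",
    "filament_spec",
    "add_isotropic_noise",
    "tilt_truncated_distribution",
    "direction_counts",
    "inverse_count_power",
    "apply_preferred_orientation_noise",
]


@dataclass
class PhantomSpec:
    """Sum-of-Gaussians phantom: centers (voxels, x/y/z), widths (Å), amplitudes."""

    centers: np.ndarray  # (k, 3) voxel coordinates (x, y, z)
    sigmas: np.ndarray  # (k,) Å, all > 0
    amplitudes: np.ndarray  # (k,) density units

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if self.centers.shape[0] == 0:
            raise ValueError("phantom spec needs at least one component")
        if np.any(self.sigmas <= 0):
            raise ValueError("all sigmas must be positive")
        k = self.centers.shape[0]
        if self.sigmas.size == 1:
            self.sigmas = np.full(k, self.sigmas[0])
        if self.amplitudes.size == 1:
            self.amplitudes = np.full(k, self.amplitudes[0])


@dataclass
class OrientationDistribution:
    """Effective particle counts N_j per orientation on an OrientationGrid."""

    grid: OrientationGrid
    counts: np.ndarray  # (n_elev, n_az), >= 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("effective counts must be non-negative")
        if not np.any(self.counts > 0):
            raise ValueError("at least one orientation must have a positive count")


def globular_spec(n: int, sigma: float = 3.0, n_components: int = 20) -> PhantomSpec:
    """Isotropic cluster of Gaussians mimicking a globular particle.

    Component positions are a fixed quasi-random cloud of radius 0.12·N
    voxels around the box center; the preset is deterministic.
    """
    rng = np.random.default_rng(20240402)  # fixed: presets are deterministic
    c = (n - 1) / 2.0
    pts = rng.normal(size=(n_components, 3))
    pts *= 0.12 * n * rng.uniform(0.2, 1.0, size=(n_components, 1)) ** (1 / 3) / (
        np.linalg.norm(pts, axis=1, keepdims=True)
    )
    return PhantomSpec(c + pts, np.full(n_components, sigma), np.ones(n_components))


def filament_spec(n: int, sigma: float = 3.0, n_components: int = 30) -> PhantomSpec:
    """Narrow filament along z: collinear chain spanning ~0.55·N voxels."""
    c = (n - 1) / 2.0
    z = c + np.linspace(-0.28 * n, 0.28 * n, n_components)
    centers = np.column_stack([np.full(n_components, c), np.full(n_components, c), z])
    return PhantomSpec(centers, np.full(n_components, sigma), np.ones(n_components))


def gaussian_phantom(spec: PhantomSpec, n: int, voxel_size: float = 1.0) -> VolumeGrid:
    """Render a sum of isotropic 3D Gaussians on an N³ grid (deterministic).

    Components must sit inside the interior of the default solvent mask
    (radius 0.4·N minus the soft edge); a component whose 3σ sphere pokes
    into the solvent shell triggers a warning, one outside the box an error.
    """
    centers = spec.centers
    if np.any(centers < 0) or np.any(centers > n - 1):
        raise ValueError("phantom component center outside the box")
    sig_vox = spec.sigmas / voxel_size
    c = (n - 1) / 2.0
    interior = DEFAULT_RADIUS_FRACTION * n - DEFAULT_EDGE_VOXELS
    reach = np.linalg.norm(centers - c, axis=1) + 3 * sig_vox
    if np.any(reach > interior):
        warnings.warn(
            "phantom extends into the solvent shell of the default mask "
            f"(max reach {reach.max():.1f} vs interior radius {interior:.1f} voxels)",
            stacklevel=2,
        )
    ax = np.arange(n, dtype=float)
    data = np.zeros((n, n, n))
    for (cx, cy, cz), s, amp in zip(centers, sig_vox, spec.amplitudes):
        gx = np.exp(-((ax - cx) ** 2) / (2 * s**2))
        gy = np.exp(-((ax - cy) ** 2) / (2 * s**2))
        gz = np.exp(-((ax - cz) ** 2) / (2 * s**2))
        data += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return VolumeGrid(data, voxel_size)


def add_isotropic_noise(
    volume: VolumeGrid, sigma: float, seed: int | np.random.Generator = 0
) -> VolumeGrid:
    """Add i.i.d. Gaussian voxel noise of standard deviation ``sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return volume.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    noise = rng.normal(scale=sigma, size=volume.data.shape)
    return VolumeGrid(volume.data + noise, volume.voxel_size, volume.origin.copy())


def tilt_truncated_distribution(
    grid: OrientationGrid,
    base_count: float = 1000.0,
    tilt_cutoff: float = 70.0,
    keep_fraction: float = 0.05,
) -> OrientationDistribution:
    """View distribution with side views depleted above a tilt cutoff.

    Tilt is measured from the pole (reconstruction-software convention),
    so ``tilt = 90° − |elevation|``.  Orientations with tilt above
    ``tilt_cutoff`` (i.e. |elevation| below ``90° − tilt_cutoff``) keep
    only ``keep_fraction`` of ``base_count`` particles; all others keep the
    full count.  The defaults mimic removing 95% of particles with tilt
    above 70°.
    """
    if not 0 <= keep_fraction <= 1:
        raise ValueError(f"keep_fraction must be in [0, 1], got {keep_fraction}")
    elev_deg = np.degrees(np.abs(grid.elevations))
    tilt = 90.0 - elev_deg
    reduced = tilt > tilt_cutoff
    counts = np.where(reduced[:, None], keep_fraction * base_count, base_count)
    counts = np.broadcast_to(counts, grid.shape).copy()
    return OrientationDistribution(grid, counts)


def direction_counts(
    dist: OrientationDistribution,
    n: int,
    plane_tolerance: float | None = None,
) -> np.ndarray:
    """Aggregate slice coverage C(k̂) on the N³ Fourier grid.

    For each Fourier voxel direction k̂, ``C`` sums the effective counts
    N_j of all orientations j whose central plane passes within
    ``plane_tolerance`` of k̂ (``|k̂·n̂_j| < tol``).  The default tolerance,
    sin of half the orientation-grid step, matches the discretization of
    the distribution grid.  Each orientation is weighted by cos(elevation),
    the solid-angle area of its grid cell: grid points crowd near the poles
    on a regular elevation/azimuth grid, and without the area weight a
    uniform per-cell distribution would not correspond to a uniform view
    density on the sphere (and would not yield isotropic noise).  The DC
    voxel gets C = 0.
    """
    grid = dist.grid
    if plane_tolerance is None:
        plane_tolerance = np.sin(0.5 * grid.elevation_step)
    normals = grid.normals().reshape(-1, 3)
    area = np.broadcast_to(
        np.cos(grid.elevations)[:, None], grid.shape
    ).ravel()
    counts = dist.counts.ravel() * area
    idx = np.arange(n) - n // 2
    kz, ky, kx = np.meshgrid(idx, idx, idx, indexing="ij")
    k = np.column_stack([kx.ravel(), ky.ravel(), kz.ravel()]).astype(float)
    r = np.linalg.norm(k, axis=1)
    out = np.zeros(n**3)
    nonzero = np.flatnonzero(r > 0)
    normals_t = normals.T
    chunk = max(1, (1 << 22) // max(1, len(counts)))
    for lo in range(0, nonzero.size, chunk):
        sel = nonzero[lo : lo + chunk]
        dirs = k[sel] / r[sel, None]
        near = np.abs(dirs @ normals_t) < plane_tolerance
        out[sel] = near @ counts
    return out.reshape(n, n, n)


def inverse_count_power(
    dist: OrientationDistribution, n: int, plane_tolerance: float | None = None
) -> np.ndarray:
    """Expected noise-power field 1/C(k̂) (0 where C = 0), DC-centered."""
    c = direction_counts(dist, n, plane_tolerance)
    with np.errstate(divide="ignore"):
        return np.where(c > 0, 1.0 / np.where(c > 0, c, 1.0), 0.0)


def apply_preferred_orientation_noise(
    volume: VolumeGrid,
    dist: OrientationDistribution,
    noise_scale: float = 1.0,
    seed: int | np.random.Generator = 0,
    plane_tolerance: float | None = None,
) -> VolumeGrid:
    """Add Fourier-domain noise whose power follows the view distribution.

    The Fourier noise standard deviation at direction k̂ is
    ``noise_scale / sqrt(C(k̂))`` with C from :func:`direction_counts`.
    The noise is built by spectrally weighting real white noise, so
    Hermitian symmetry is exact and the output map is real.  Directions
    with C = 0 (no covering slices at all) receive no noise — they model
    truly empty Fourier regions — and their count is reported via a
    warning.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = volume.n
    c = direction_counts(dist, n, plane_tolerance)
    empty = (c == 0).sum() - 1  # DC is always zero by construction
    if empty > 0:
        warnings.warn(
            f"{int(empty)} Fourier voxels have no covering slice (left noise-free)",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        weight = np.where(c > 0, noise_scale / np.sqrt(np.where(c > 0, c, 1.0)), 0.0)
    white = rng.normal(size=(n, n, n))
    spectrum = np.fft.fftshift(np.fft.fftn(white)) / np.sqrt(n**3)
    noise = np.fft.ifftn(np.fft.ifftshift(spectrum * weight)).real
    return VolumeGrid(volume.data + noise, volume.voxel_size, volume.origin.copy())
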