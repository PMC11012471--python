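"""Fourier-space bookkeeping: transforms, shells, cones and central slices.

All frequency-domain arrays are DC-centered (``fftshift`` layout) and
indexed ``[z, y, x]`` like the real-space grids.  Physical frequencies are
in 1/Å; the Nyquist frequency is ``1/(2·voxel_size)`` and the corresponding
"Nyquist resolution" is ``2·voxel_size`` Å.

Orientations follow the elevation/azimuth convention used throughout the
package: elevation is measured from the equatorial plane, so elevation 0
is a side view and elevation ±π/2 is a top view (the pole).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import ndimage

from .volume_io import VolumeGrid

__all__ = [
    "FourierVolume",
    "OrientationGrid",
    "CentralSlice",
    "forward_fft",
    "slice_normal",
    "inplane_basis",
    "frequency_grid",
    "extract_central_slice",
    "SlicePowerSampler",
    "shell_index",
    "cone_membership",
    "fibonacci_hemisphere",
]


@dataclass
class FourierVolume:
    """Unnormalized DFT of a cubic map, DC-centered.

    ``coefficients`` is the complex ``(N, N, N)`` array produced by
    ``fftshift(fftn(data))``; Parseval's identity then reads
    ``sum(data**2) == sum(|coefficients|**2) / N**3``.
    """

    coefficients: np.ndarray
    voxel_size: float

    @property
    def n(self) -> int:
        return self.coefficients.shape[0]

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in 1/Å."""
        return 1.0 / (2.0 * self.voxel_size)

    @property
    def frequency_step(self) -> float:
        """Frequency-grid spacing 1/(N·voxel_size) in 1/Å."""
        return 1.0 / (self.n * self.voxel_size)

    @cached_property
    def power(self) -> np.ndarray:
        """Squared modulus of the Fourier coefficients."""
        return np.abs(self.coefficients) ** 2


@dataclass
class OrientationGrid:
    """Regular elevation × azimuth grid of slice-normal directions."""

    elevations: np.ndarray  # radians in [-pi/2, pi/2]
    azimuths: np.ndarray  # radians in [0, 2*pi)

    def __post_init__(self) -> None:
        self.elevations = np.asarray(self.elevations, dtype=float)
        self.azimuths = np.asarray(self.azimuths, dtype=float)

    @classmethod
    def regular(
        cls, elev_step: float = np.pi / 60, az_step: float = np.pi / 60
    ) -> "OrientationGrid":
        """Grid with the given angular steps (default 3° on both axes)."""
        n_el = int(round(np.pi / elev_step))
        elevations = -np.pi / 2 + elev_step * np.arange(n_el + 1)
        n_az = int(round(2 * np.pi / az_step))
        azimuths = az_step * np.arange(n_az)
        return cls(elevations, azimuths)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.elevations), len(self.azimuths)

    @property
    def elevation_step(self) -> float:
        return float(np.diff(self.elevations).mean())

    def normals(self) -> np.ndarray:
        """Unit normals for every grid point, shape ``(n_elev, n_az, 3)``."""
        el = self.elevations[:, None]
        az = self.azimuths[None, :]
        return np.stack(
            [
                np.cos(el) * np.cos(az),
                np.cos(el) * np.sin(az),
                np.sin(el) * np.ones_like(az),
            ],
            axis=-1,
        )


@dataclass
class CentralSlice:
    """Band-limited power samples on the central plane ⟂ a slice normal."""

    elevation: float
    azimuth: float
    samples: np.ndarray  # interpolated power values
    frequencies: np.ndarray  # 1/Å per sample
    points: np.ndarray  # (n, 3) physical frequency coordinates (x, y, z)

    @property
    def mean_power(self) -> float:
        return float(self.samples.mean())


def forward_fft(volume: VolumeGrid) -> FourierVolume:
    """DC-centered unnormalized FFT of a real map."""
    if not np.isfinite(volume.data).all():
        raise ValueError("non-finite values in volume data")
    coeffs = np.fft.fftshift(np.fft.fftn(volume.data.astype(np.float64)))
    return FourierVolume(coeffs, volume.voxel_size)


def slice_normal(elevation: float, azimuth: float) -> np.ndarray:
    """Unit normal (x, y, z) of the central slice at (elevation, azimuth).

    ``n = (cos e·cos a, cos e·sin a, sin e)``; elevation ±π/2 gives the
    top-view normal (0, 0, ±1), elevation 0 an equatorial (side-view) one.
    """
    if not (np.isfinite(elevation) and np.isfinite(azimuth)):
        raise ValueError("angles must be finite")
    ce = np.cos(elevation)
    return np.array([ce * np.cos(azimuth), ce * np.sin(azimuth), np.sin(elevation)])


def inplane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis (u, v) for a slice normal.

    Chosen so that ``u(-n) = -u(n)`` and ``v(-n) = v(n)``: together with an
    even number of angular samples per ring this makes antipodal slices
    sample exactly the same point set, so the power centrosymmetry of real
    maps is preserved to round-off by the sampler.
    """
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("degenerate (zero) normal")
    n = n / norm
    helper = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(helper, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def frequency_grid(n: int, voxel_size: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Broadcastable (kz, ky, kx) physical-frequency axes, DC-centered, 1/Å."""
    f = np.fft.fftshift(np.fft.fftfreq(n, d=voxel_size))
    return f[:, None, None], f[None, :, None], f[None, None, :]


def _ring_samples(
    n: int, voxel_size: float, rmin: float, rmax: float
) -> tuple[np.ndarray, np.ndarray]:
    """In-plane sample coordinates for concentric rings in a resolution band.

    Returns ``(pts2, freqs)`` where ``pts2`` has columns (f·cosθ, f·sinθ) in
    1/Å.  Rings sit on multiples of the frequency step and the angular step
    is chosen so the arc length between samples is about one frequency-grid
    voxel; the per-ring sample count is forced even so each ring is an
    exactly centrosymmetric point set.
    """
    if not rmin > rmax:
        raise ValueError(
            f"rmin must exceed rmax in Å (low-resolution bound first); "
            f"got rmin={rmin}, rmax={rmax}"
        )
    nyq = 1.0 / (2.0 * voxel_size)
    fmin, fmax = 1.0 / rmin, 1.0 / rmax
    if fmax > nyq * (1 + 1e-9):
        raise ValueError(f"rmax={rmax} Å is beyond Nyquist ({2 * voxel_size} Å)")
    df = 1.0 / (n * voxel_size)
    radii = df * np.arange(1, n // 2 + 1)
    radii = radii[(radii >= fmin - 1e-9 * df) & (radii <= fmax + 1e-9 * df)]
    if radii.size == 0:
        raise ValueError(f"band ({rmin} Å, {rmax} Å) is empty at grid size {n}")
    pts, freqs = [], []
    for f in radii:
        m = 2 * max(4, int(np.ceil(np.pi * f / df)))
        theta = 2 * np.pi * np.arange(m) / m
        pts.append(np.column_stack([f * np.cos(theta), f * np.sin(theta)]))
        freqs.append(np.full(m, f))
    return np.concatenate(pts), np.concatenate(freqs)


class SlicePowerSampler:
    """Repeated central-slice power averaging over one power volume.

    Ring sample geometry is precomputed once; each orientation costs a
    3×2 basis product and one trilinear interpolation pass.  Interpolation
    wraps at the grid edge, which matches the aliasing of the discrete
    Fourier transform at the Nyquist ring on even grids.
    """

    def __init__(self, power: np.ndarray, voxel_size: float, rmin: float, rmax: float):
        self.power = np.ascontiguousarray(power, dtype=np.float64)
        self.n = power.shape[0]
        self.voxel_size = float(voxel_size)
        self.df = 1.0 / (self.n * self.voxel_size)
        self.pts2, self.frequencies = _ring_samples(self.n, voxel_size, rmin, rmax)
        self.band = (rmin, rmax)

    def sample_points(self, elevation: float, azimuth: float) -> np.ndarray:
        """(n, 3) physical frequency coordinates of all ring samples."""
        u, v = inplane_basis(slice_normal(elevation, azimuth))
        return self.pts2 @ np.vstack([u, v])

    def sample(self, elevation: float, azimuth: float) -> np.ndarray:
        pts3 = self.sample_points(elevation, azimuth)
        # physical (x, y, z) -> fractional array index [z, y, x]
        coords = pts3[:, ::-1].T / self.df + self.n // 2
        return ndimage.map_coordinates(
            self.power, coords, order=1, mode="grid-wrap", prefilter=False
        )

    def mean_power(self, elevation: float, azimuth: float) -> float:
        return float(self.sample(elevation, azimuth).mean())

    def heatmap(self, grid: OrientationGrid) -> np.ndarray:
        """Mean slice power for every orientation of ``grid``."""
        out = np.empty(grid.shape)
        for i, e in enumerate(grid.elevations):
            for j, a in enumerate(grid.azimuths):
                out[i, j] = self.mean_power(e, a)
        return out


def extract_central_slice(
    fvol: FourierVolume,
    orientation: tuple[float, float],
    band: tuple[float, float],
    sampler: SlicePowerSampler | None = None,
) -> CentralSlice:
    """Band-limited power samples on the central plane at ``orientation``.

    ``band`` is ``(rmin, rmax)`` in Å with rmin the low-resolution (larger)
    bound.  Pass a prebuilt ``sampler`` when extracting many slices from the
    same volume.
    """
    elevation, azimuth = orientation
    if sampler is None:
        sampler = SlicePowerSampler(fvol.power, fvol.voxel_size, *band)
    samples = sampler.sample(elevation, azimuth)
    points = sampler.sample_points(elevation, azimuth)
    return CentralSlice(elevation, azimuth, samples, sampler.frequencies.copy(), points)


def shell_index(n: int, n_shells: int) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-shell assignment for every Fourier voxel below Nyquist.

    Shell centers are spaced uniformly from DC to the Nyquist radius
    (``n/2`` index units).  Returns ``(assignment, radii)`` where
    ``assignment`` is ``-1`` for voxels beyond Nyquist and ``radii`` gives
    each shell's center radius in index units (multiply by ``1/(n·voxel)``
    for 1/Å).
    """
    if n_shells < 2:
        raise ValueError("n_shells must be at least 2")
    idx = np.arange(n) - n // 2
    r = np.sqrt(
        idx[:, None, None] ** 2 + idx[None, :, None] ** 2 + idx[None, None, :] ** 2
    )
    r_nyq = n / 2
    scale = (n_shells - 1) / r_nyq
    assignment = np.rint(r * scale).astype(np.int32)
    assignment[r > r_nyq] = -1
    radii = np.arange(n_shells) / scale
    return assignment, radii


def cone_membership(
    n: int, axis: np.ndarray, half_angle: float
) -> np.ndarray:
    """Boolean field of Fourier voxels within ``half_angle``° of an axis line.

    Membership uses the angle between *lines* (direction sign ignored), so
    Friedel mates are included by construction.  Boundary voxels are
    members (inclusive ≤).  The DC voxel has no direction and is excluded.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("zero cone axis")
    if not 0 < half_angle <= 90:
        raise ValueError(f"half_angle must be in (0, 90], got {half_angle}")
    a = axis / norm
    idx = np.arange(n) - n // 2
    kz = idx[:, None, None]
    ky = idx[None, :, None]
    kx = idx[None, None, :]
    dot = np.abs(kx * a[0] + ky * a[1] + kz * a[2])
    r = np.sqrt(kx**2 + ky**2 + kz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(r > 0, dot / np.where(r > 0, r, 1.0), 0.0)
    member = cosang >= np.cos(np.radians(half_angle)) - 1e-12
    member[n // 2, n // 2, n // 2] = False
    return member


def fibonacci_hemisphere(n_axes: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the upper hemisphere, shape (n_axes, 3).

    Golden-angle spiral in z ∈ [0, 1); the standard low-discrepancy choice
    for cone-axis sampling.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be positive")
    i = np.arange(n_axes)
    z = (i + 0.5) / n_axes
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z**2)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
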