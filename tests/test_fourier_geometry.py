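import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapaniso import (
    VolumeGrid,
    OrientationGrid,
    forward_fft,
    slice_normal,
    extract_central_slice,
    shell_index,
    cone_membership,
    fibonacci_hemisphere,
)
from mapaniso.fourier_geometry import SlicePowerSampler, inplane_basis

from conftest import trilinear_wrap


class TestForwardFFT:
    def test_constant_map_all_power_at_dc(self):
        n, c = 16, 2.5
        fv = forward_fft(VolumeGrid(np.full((n,) * 3, c), 1.0))
        center = n // 2
        assert fv.power[center, center, center] == pytest.approx((c * n**3) ** 2)
        off_dc = fv.power.copy()
        off_dc[center, center, center] = 0
        assert off_dc.max() < 1e-12 * fv.power.max()

    def test_hermitian_symmetry_of_real_input(self, noise_volume):
        f = forward_fft(noise_volume).coefficients
        # F(-k) = conj(F(k)): point-reflect the DC-centered grid
        flipped = f[::-1, ::-1, ::-1]
        flipped = np.roll(flipped, 1, axis=(0, 1, 2))  # even-N center alignment
        resid = np.abs(flipped - np.conj(f)).max()
        assert resid < 1e-6 * np.abs(f).max()

    def test_parseval_identity(self, noise_volume):
        fv = forward_fft(noise_volume)
        n3 = noise_volume.n**3
        lhs = np.sum(noise_volume.data.astype(np.float64) ** 2)
        rhs = fv.power.sum() / n3
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_non_finite_rejected(self):
        v = VolumeGrid(np.zeros((16,) * 3), 1.0)
        v.data[0, 0, 0] = np.inf  # bypass constructor validation
        with pytest.raises(ValueError):
            forward_fft(v)


class TestSliceNormal:
    def test_top_view_pole(self):
        np.testing.assert_allclose(slice_normal(np.pi / 2, 1.234), [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(slice_normal(-np.pi / 2, 0.4), [0, 0, -1], atol=1e-12)

    def test_equatorial_normals(self):
        np.testing.assert_allclose(slice_normal(0, 0), [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(slice_normal(0, np.pi / 2), [0, 1, 0], atol=1e-12)

    @given(
        e=st.floats(-np.pi / 2, np.pi / 2),
        a=st.floats(0, 2 * np.pi),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_unit_norm(self, e, a):
        assert np.linalg.norm(slice_normal(e, a)) == pytest.approx(1.0, abs=1e-12)

    @given(
        e=st.floats(-np.pi / 2, np.pi / 2),
        a=st.floats(0, 2 * np.pi),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_inplane_basis_orthonormal_and_antipodal(self, e, a):
        n = slice_normal(e, a)
        u, v = inplane_basis(n)
        for a_, b_ in [(u, u), (v, v)]:
            assert a_ @ b_ == pytest.approx(1.0, abs=1e-12)
        assert abs(u @ v) < 1e-12 and abs(u @ n) < 1e-12 and abs(v @ n) < 1e-12
        u2, v2 = inplane_basis(-n)
        np.testing.assert_allclose(u2, -u, atol=1e-12)
        np.testing.assert_allclose(v2, v, atol=1e-12)


class TestCentralSlice:
    def test_isotropic_noise_equal_power_across_orientations(self, rng):
        v = VolumeGrid(rng.normal(size=(64,) * 3), 1.0)
        fv = forward_fft(v)
        sampler = SlicePowerSampler(fv.power, 1.0, 10.0, 2.0)
        means = [
            sampler.mean_power(e, a)
            for e, a in zip(
                rng.uniform(-np.pi / 2, np.pi / 2, 100), rng.uniform(0, 2 * np.pi, 100)
            )
        ]
        means = np.array(means)
        assert means.std() / means.mean() < 0.05

    def test_z_cone_power_read_by_slices_containing_the_axis(self):
        """Power confined to a z-axis cone is read by equatorial-normal slices.

        A slice's plane is perpendicular to its orientation normal, so the
        elevation-0 slice contains the z axis and intersects the cone,
        while the elevation-π/2 slice is the equatorial plane and misses it.
        Oracle: brute-force per-voxel cone membership on a 32³ grid builds
        the power field directly.
        """
        n = 32
        member = cone_membership(n, [0, 0, 1], 30.0)
        fv_power = member.astype(float)
        sampler = SlicePowerSampler(fv_power, 1.0, 10.0, 2.0)
        polar = sampler.mean_power(np.pi / 2, 0.0)
        equatorial = sampler.mean_power(0.0, 0.0)
        assert equatorial > polar

    def test_band_containment(self, rng):
        v = VolumeGrid(rng.normal(size=(64,) * 3), 1.0)
        fv = forward_fft(v)
        s = extract_central_slice(fv, (0.3, 1.1), (10.0, 2.0))
        assert s.frequencies.min() >= 0.1 - 1e-9
        assert s.frequencies.max() <= 0.5 + 1e-9
        assert len(s.samples) > 0

    def test_matches_independent_trilinear_interpolation(self, rng):
        """Slice samples equal a hand-rolled wrap-around trilinear oracle."""
        n = 32
        v = VolumeGrid(rng.normal(size=(n,) * 3), 1.0)
        fv = forward_fft(v)
        sampler = SlicePowerSampler(fv.power, 1.0, 10.0, 2.0)
        for e, a in [(0.4, 1.0), (np.pi / 2, 0.0), (-0.7, 4.5)]:
            s = extract_central_slice(fv, (e, a), (10.0, 2.0), sampler=sampler)
            idx = s.points[:, ::-1] / sampler.df + n // 2
            expected = trilinear_wrap(fv.power, idx)
            assert abs(s.samples.mean() - expected.mean()) <= 1e-6 * expected.mean()

    def test_empty_band_rejected(self, noise_volume):
        fv = forward_fft(noise_volume)
        with pytest.raises(ValueError, match="band|rmin"):
            extract_central_slice(fv, (0, 0), (2.0, 10.0))  # rmin < rmax: invalid

    def test_degenerate_normal_rejected(self):
        with pytest.raises(ValueError, match="degenerate|zero"):
            inplane_basis([0.0, 0.0, 0.0])


class TestShellIndex:
    def test_dc_voxel_in_shell_zero(self):
        shells, radii = shell_index(32, 17)
        assert shells[16, 16, 16] == 0
        assert radii[0] == 0

    def test_shell_radii_monotone_and_populations_grow(self):
        shells, radii = shell_index(64, 33)
        assert np.all(np.diff(radii) > 0)
        pops = np.bincount(shells[shells >= 0].ravel())
        # r² growth trend over interior shells
        assert np.all(np.diff(pops[1:28]) > 0)

    def test_all_voxels_below_nyquist_assigned(self):
        n = 32
        shells, _ = shell_index(n, 17)
        idx = np.arange(n) - n // 2
        r = np.sqrt(
            idx[:, None, None] ** 2 + idx[None, :, None] ** 2 + idx[None, None, :] ** 2
        )
        assert (shells >= 0).sum() == (r <= n / 2).sum()

    def test_too_few_shells_rejected(self):
        with pytest.raises(ValueError):
            shell_index(32, 1)


class TestConeMembership:
    def test_axis_voxels_and_friedel_mates_are_members(self):
        n = 32
        m = cone_membership(n, [0, 0, 1], 20.0)
        assert m[n // 2 + 5, n // 2, n // 2]  # +z
        assert m[n // 2 - 5, n // 2, n // 2]  # -z (Friedel mate)

    def test_equatorial_voxels_excluded(self):
        n = 32
        m = cone_membership(n, [0, 0, 1], 89.0)
        assert not m[n // 2, n // 2 + 7, n // 2]
        assert not m[n // 2, n // 2, n // 2 + 7]

    def test_dc_excluded(self):
        m = cone_membership(32, [0, 0, 1], 20.0)
        assert not m[16, 16, 16]

    def test_solid_angle_fraction(self):
        """Member fraction of a shell ≈ 1 − cos(half-angle), the double-cone
        solid-angle closed form."""
        n = 64
        m = cone_membership(n, [0, 0, 1], 20.0)
        shells, _ = shell_index(n, n // 2 + 1)
        frac = m[shells == 20].mean()
        expected = 1 - np.cos(np.radians(20))
        assert frac == pytest.approx(expected, rel=0.10)

    def test_matches_bruteforce_angle_test(self):
        """Exact agreement with a per-voxel scalar angle computation on 32³."""
        n = 32
        axis = np.array([1.0, 2.0, -0.5])
        axis /= np.linalg.norm(axis)
        half = 25.0
        m = cone_membership(n, axis, half)
        brute = np.zeros((n, n, n), dtype=bool)
        for iz in range(n):
            for iy in range(n):
                for ix in range(n):
                    k = np.array([ix - n // 2, iy - n // 2, iz - n // 2], float)
                    r = np.linalg.norm(k)
                    if r == 0:
                        continue
                    ang = np.degrees(np.arccos(min(1.0, abs(k @ axis) / r)))
                    brute[iz, iy, ix] = ang <= half + 1e-9
        np.testing.assert_array_equal(m, brute)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            cone_membership(32, [0, 0, 0], 20.0)


def test_fibonacci_hemisphere_unit_and_upper():
    axes = fibonacci_hemisphere(100)
    np.testing.assert_allclose(np.linalg.norm(axes, axis=1), 1.0, atol=1e-12)
    assert np.all(axes[:, 2] >= 0)


def test_power_centrosymmetry_of_antipodal_slices(rng):
    """Mean power at (e, a) equals that at (−e, a+π): same plane, and the
    ring construction samples the identical point set."""
    v = VolumeGrid(rng.normal(size=(32,) * 3), 1.0)
    fv = forward_fft(v)
    sampler = SlicePowerSampler(fv.power, 1.0, 10.0, 2.0)
    for e, a in [(0.5, 0.7), (1.2, 3.0), (0.0, 2.0)]:
        p1 = sampler.mean_power(e, a)
        p2 = sampler.mean_power(-e, (a + np.pi) % (2 * np.pi))
        assert abs(p1 - p2) < 1e-6 * p1
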