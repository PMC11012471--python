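# Methods

## The noise model

A gridding-based single-particle reconstruction assembles each Fourier
value of the map as a weighted average of the particle-image transforms
whose central slices pass near it. Writing `N_j` for the effective number
of particles contributing at orientation `j` (weights included), the
averaged noise at that orientation has residual power proportional to
`1/N_j`. The macromolecular signal rides on top of this noise field and is
shaped by the particle itself; the noise field is not. Removing the
particle with a solvent mask therefore isolates a quantity whose
directional structure reflects only the view distribution.

The estimator samples the masked map's Fourier power on central slices.
A slice at orientation `(elevation e, azimuth a)` is the plane through DC
perpendicular to the unit normal

```
n = (cos e · cos a,  cos e · sin a,  sin e),
```

elevation measured from the equatorial plane (`e = 0`: side view;
`e = ±π/2`: top view; note this differs from the tilt convention of
reconstruction software, whose origin is at the pole: `tilt = 90° − |e|`).
Per orientation the power samples within the resolution band are averaged
(`NP̄_j`) and the grid is normalized by its maximum (`NP_j`), so the output
is scale-free: multiplying the map by any constant leaves the heatmap
unchanged, and `max NP_j = 1` always.

Interpretation is relative, not absolute: ridges of high `NP_j` mark
starved orientations. Orientations with `NP_j` below a small threshold
(default 1% of the maximum) are flagged as *empty*: there the Fourier
region is not merely noisy but unfilled (missing-wedge-like), gridding
interpolation cannot have filled it, and the `1/N_j` reading is not
meaningful.

### Assumptions

- the input is a raw reconstruction: no sharpening, masking, density
  modification, or subtracted/sub-particle refinement (all of which alter
  the solvent noise);
- the reconstruction filled Fourier space by gridding interpolation, so
  zero-count orientations still received (interpolated) noise except where
  whole regions are empty;
- the solvent shell contains no ordered signal (choose the mask radius
  accordingly).

## Central-slice sampling

Slices are sampled on concentric rings at the frequency-grid spacing
`df = 1/(N·voxel)`, with the angular step chosen so the arc between
samples is about one frequency voxel (near-uniform area weighting); the
per-ring count is forced even. Power — not complex coefficients — is
interpolated trilinearly; interpolating power avoids the phase-cancellation
bias that complex interpolation would introduce, at the cost of a small
orientation-dependent smoothing bias (relative spread below ~1% on smooth
spectra), which cancels in the normalized, rank-based readings the method
relies on. Interpolation wraps at the grid edge, matching the aliasing of
the DFT at the Nyquist ring on even grids.

The in-plane ring basis is constructed so that antipodal normals sample
*exactly* the same point set (`u(−n) = −u(n)`, `v(−n) = v(n)`, even ring
counts). Since `|V(−k)|² = |V(k)|²` exactly for real maps, the heatmap's
centrosymmetry `NP(e, a) = NP(−e, a+π)` holds to round-off, not merely to
sampling error.

The mean over the band is taken over all ring samples (area-weighted
frequencies), rather than as a mean of per-ring means; the two readings
differ only in how rings are weighted and agree in rank structure.

## Parameters and defaults

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `rmin` | 10 | Å | excludes low frequencies where particle signal leaks through the soft mask edge |
| `rmax` | Nyquist (`2·voxel`) | Å | use the full noise-dominated band |
| orientation grid | 3° × 3° | — | resolves the view-distribution features seen in practice at acceptable cost (7320 slices) |
| solvent mask radius | `0.4·N` | voxels | keeps particles up to ~0.8 of the box masked out while retaining a solvent shell |
| mask edge | 5 | voxels | raised-cosine (half-cosine) ramp; standard soft-masking width |
| empty-flag epsilon | 0.01 | relative | "zero or near-zero" quantified conservatively |
| cone half-angle | 20 | degrees | double cone about the axis line (Friedel-symmetric), the conventional choice |
| cone axes | 200 | — | Fibonacci-sphere hemisphere sampling |
| FSC thresholds | 0.143, 0.5 | — | half-map and map-vs-model conventions |

Numerical tie-breaks: voxels exactly on a cone or shell boundary are
included (≤); shell assignment is nearest-center on a uniform radius grid
up to Nyquist; FSC shells whose power falls below 10⁻¹² of the strongest
shell are reported as 0 with a warning (an exactly emptied region stored
as float32 reacquires ~10⁻¹⁴ relative power, so an exact-zero test would
never fire). `fsc_resolution` interpolates the threshold crossing linearly
in frequency and returns the Nyquist resolution, flagged, when no crossing
occurs.

## Sphericity

The directional-FSC volume assigns each Fourier voxel the FSC of its shell
and the inverse-angle-weighted average of its three nearest cone axes.
Binarized at 0.143 or 0.5, the connected component containing DC defines
the region (detached suprathreshold blobs are artefacts of noisy cone
curves and are excluded). Sphericity is `π^(1/3)·(6V)^(2/3)/A` with `V`
the voxel count and `A` the area of a marching-cubes mesh relaxed by 10
Taubin smoothing passes. Raw marching cubes on a binary region produces a
voxel staircase whose area is inflated by up to ~8% — enough to push a
perfect digitized ball to ~0.92 — while Taubin relaxation removes the
staircase with negligible volume shrinkage: a radius-20 ball measures
0.98, a digitized prolate spheroid (10, 10, 30) agrees with the analytic
closed form to ~2%, and a cube lands within 3% of `π^(1/3)·6^(2/3)/6 ≈
0.806`. More smoothing passes would round genuine edges (the cube drifts
upward); fewer leave staircase residue (the ball falls).

## The synthetic generator

`gaussian_phantom` renders deterministic sums of isotropic 3D Gaussians:
a globular preset (quasi-random cluster of 20 Gaussians, radius 0.12·N)
and a filament preset (30 collinear Gaussians along z spanning 0.55·N) —
the two shape extremes for which directional-resolution metrics diverge.
A long z-filament transforms to a pancake concentrated near the `kz = 0`
plane, so its *signal* power is strongly directional even when its noise
is perfectly isotropic; this is precisely the confound the solvent-noise
estimator removes.

`apply_preferred_orientation_noise` injects the noise consequence of a
biased view distribution without running a reconstruction. The coverage of
Fourier direction `k̂` is aggregated as

```
C(k̂) = Σ_j  cos(e_j) · N_j · [ |k̂ · n̂_j| < sin(step/2) ],
```

a discrete great-circle integral of the view density: an orientation
contributes wherever its central plane passes within half a grid step of
`k̂`. The `cos(e_j)` factor is each cell's solid angle on the regular
elevation/azimuth grid — without it, per-cell-uniform counts would
overweight the poles and a nominally uniform distribution would produce
anisotropic noise. White real-space noise is then spectrally reweighted to
standard deviation `noise_scale/√C(k̂)` per Fourier coefficient, which
keeps Hermitian symmetry exact (the output map is real). Directions with
`C = 0` are left noise-free and reported: they model truly empty regions.
Note `noise_scale` is a Fourier-domain scale per unit effective count; the
resulting real-space noise variance is `noise_scale² · mean(1/C)`, small
when counts are large, so when mixing with voxel noise choose scales
deliberately.

`tilt_truncated_distribution` reproduces the standard artificial-anisotropy
protocol: particles with tilt above a cutoff (pole-origin convention, i.e.
`|elevation| < 90° − cutoff`) are reduced to a `keep_fraction` (default:
cutoff 70°, keep 5% — a 20-fold depletion of side views).

### What the generator does and does not emulate

It reproduces the directional noise-power structure that the estimator
senses, with exact control of the injected `1/C` field — enabling
end-to-end parameter-recovery tests (rank correlation between heatmap and
injected inverse coverage > 0.9, contrast monotone in truncation
severity). It does **not** run projection/backprojection: CTFs, gridding
kernel side-effects, real-space artefacts of severe anisotropy (map
stretching), alignment errors, and structured solvent are all absent.
Passing tests therefore demonstrate the estimator's fidelity to the noise
model, not robustness to every pathology of experimental maps.

## Problem sizes and study conditions

The isotropy study runs at the full working size (128³, 1 Å/voxel, 3°
grid, SNR ≈ 1, five seeds in the acceptance script): at this size the
median normalized heatmap value measures ~0.96, consistent with the
"almost constant, near 0.95" level expected of an isotropic map (the
median sits below 1 exactly because the normalizer is the *maximum* of
thousands of correlated sampling means). The shape-contrast study
(filament vs globular at matched noise realization, unit-RMS phantoms)
runs at 96³: at 64³ the globular per-cone FSC spread is dominated by the
finite cone∩shell sampling floor (≈1/√n per cone-shell) rather than
shape, and the contrast between the two phantoms (measured ≈3× in maximal
per-cone std, with both noise heatmaps flat to < 0.05 std) would be
understated. Parameter-recovery runs use 64³ with a 6° distribution grid.

## Known limitations

- The method diagnoses the *presence* of preferred orientations, not
  their impact on map quality; per-cone FSC remains the complementary
  reading for that (and is shape-confounded across specimens).
- Post-processed, masked or subtracted maps violate the noise model; the
  CLI documents but cannot verify this user contract.
- The heatmap is relative (normalized by its own maximum); absolute
  particle counts are not recoverable.
- Near-degenerate bands (`rmin` close to `rmax`) leave few rings and
  noisy heatmaps; the band must contain at least one frequency-grid ring.
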