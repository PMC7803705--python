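# Methods

`eptpipe` implements Helmholtz-based MR electrical properties tomography
(MR-EPT) for brain conductivity, together with a synthetic data world in
which every stage of the pipeline can be tested against known ground
truth. This note documents the model, the numerical choices, and what the
synthetic world does and does not emulate.

## The reconstruction model

Where tissue electrical properties are locally homogeneous, the transmit
RF field B1+ of an MR coil satisfies a homogeneous Helmholtz equation, and
conductivity follows from the measured complex B1+ map as

    sigma(r) = Im( lap B1+(r) / B1+(r) ) / (mu0 * omega)        [S/m]

with omega the Larmor angular frequency (2*pi*128 MHz at 3 T) and
mu0 = 4*pi*1e-7 H/m. The B1+ phase is not directly measurable; it is
approximated as half the transceive phase phi+- (the transceive phase
assumption). The transceive phase itself is obtained by averaging two
spin-echo phase maps acquired with opposite readout-gradient polarities,
which cancels any phase term that is odd under polarity reversal — in
particular eddy-current ramps.

Sign conventions are fixed once: the complex wavenumber obeys
`k^2 = omega^2*mu0*eps - 1j*omega*mu0*sigma` and fields propagate as
`exp(-1j*k*(n.r))`, so `Im(lap B / B) = omega*mu0*sigma >= 0` and the
reconstruction yields positive conductivities with no sign flip. The
lossless limit (sigma = 0, real k) is the unit test of this convention.

### Derivative kernels

The Laplacian is the noise-critical step. Per axis we use the
second-derivative stencil of a least-squares quadratic fit
(Savitzky-Golay, order 2) over the kernel window; across the remaining
footprint axes the derivative is averaged uniformly. This separable
construction is the standard "large noise-robust kernel": it reproduces
the exact second derivative of any quadratic (so smooth fields are
unbiased to O(h^2)) while averaging down noise over the footprint. The
in-plane default is a 7x7 window (half-widths 3,3,0); the full 3D variant
extends it to 7x7x3 (half-width 1 through slices — the through-slice
extent is configurable since no standard fixes it). Spacing enters the
stencils in metres, taken from the grid (or NIfTI header).

A voxel of the output is valid only if the entire kernel footprint lies
inside the foreground (head) mask; footprints straddling tissue-tissue
interfaces are *kept*, because that boundary error is the phenomenon under
study. Voxels with |B1+| below `magnitude_floor` (default 1e-6 of the
foreground maximum) are invalid (division guard). Validity is an explicit
mask carried with the map; statistics never see invalid voxels and no
sentinel values exist.

2D multi-slice phase maps carry an arbitrary constant phase per slice
(each slice is an independent excitation). A per-slice constant cancels
exactly in `lap_2D(B)/B`, so the in-plane reconstruction is invariant to
slice offsets (verified to ~1e-12 S/m); any kernel with through-slice
extent is not — which is why in vivo reconstructions must use the 2D
kernel and consequently miss the through-slice curvature term. For a
separable field f(x,y)g(z), that miss is exactly Im(g''/g)/(mu0*omega):
an oblique plane wave at elevation theta is under-reported by sin(theta)^2.

### Preprocessing

Order: Gibbs ringing correction, then Gaussian k-space apodization, then
the Laplacian — ringing is corrected before the spectrum is deliberately
blurred. Both operate per 2D slice.

*Gibbs correction* uses a local subvoxel-shift method, independently on
the real and imaginary channels and along each in-plane axis: every line
is resampled at 21 shifts in [-0.5, +0.5] voxel via Fourier
interpolation; per voxel, the shift minimising a 3-voxel total-variation
window is selected (ringing oscillates at the Nyquist rate, so sampling
between the oscillation extrema suppresses it) and the sampled value is
Taylor-shifted back to the voxel centre. Two details matter for EPT
specifically: the unshift includes the second-order (curvature) term,
because an O(s^2 f'') residual is exactly what the Laplacian measures;
and a voxel is only replaced when the best shift reduces its local TV by
more than 20%, so smooth ringing-free data pass through bit-identically.

*Apodization* multiplies each slice's 2D spectrum by a centred Gaussian
with sigma = 0.4 of the Nyquist radius (configurable; it trades boundary
sharpness against noise). The window is 1 at k = 0, preserving means.

### Masks and statistics

Tissue masks keep voxels with segmentation probability strictly above
0.99, excluding partial-volume voxels. Boundary-error exclusion then
erodes each slice independently (never through slices, matching the 2D
acquisition) with the exact Euclidean disk of radius 2 (13 offsets);
image borders count as background. Per-tissue mean and standard deviation
(population convention, n in the denominator; configurable) are computed
over valid voxels only; a tissue whose mask is empty is omitted with a
logged warning — the analogue of the empty eroded-CSF entries in vivo.
Across "subjects" (noise seeds), the aggregate is the unweighted mean of
per-run means, not the pooled-voxel mean.

## The synthetic world

No in vivo data are available, so the generator supplies the study
conditions end to end:

- **Phantom**: nested ellipsoidal shells — CSF shell, GM shell, WM core —
  on a 96x96x36 grid at 2.5 mm isotropic (240x240x90 mm field of view),
  outer semi-axes 95x105x42.5 mm. Literature ex vivo conductivities at
  128 MHz: WM 0.34, GM 0.59, CSF 2.14 S/m (relative permittivities 52.5 /
  73.5 / 84). The CSF shell defaults to 12.5 mm — thin, as in vivo — and
  is configurable; the ground-truth-recovery experiment uses 15 mm so
  that eroded CSF statistics exist at all.
- **Fields**: closed forms that satisfy the Helmholtz equation exactly
  inside each compartment. The workhorse is a piecewise plane wave
  `exp(-1j*k_tissue*(n.r))`; it is deliberately *discontinuous in value*
  at interfaces, which reproduces (in exaggerated form) the boundary
  error of large derivative kernels. A J0(k*rho) cylinder field provides
  the quadrature-birdcage analytic solution as a second, independent
  oracle. The default propagation direction (1, 2, 0.745) carries a 10%
  through-slice curvature share, the magnitude of through-slice
  contribution the in-plane kernel is known to forfeit on real brain
  fields. Air carries no signal (field 0).
- **Acquisition**: per-slice 2D k-space truncation to an 80x80 matrix
  (zero-filled back) injects Gibbs ringing; complex Gaussian noise is
  added with per-channel std = mean foreground |B1+| / SNR, SNR = 50
  (this SNR definition is a package convention; sources rarely state
  one); spin-echo phase pairs get opposite eddy-current ramps (default
  0.01 rad/voxel along the readout axis) and independent random per-slice
  phase offsets (uniform in [-pi, pi]). Everything is reproducible
  bit-for-bit from one integer seed.
- **Segmentation**: per-class indicators smoothed with a 5 mm FWHM
  Gaussian and renormalised voxelwise — a geometric stand-in for a
  probabilistic segmentation. With this width the P > 0.99 threshold
  excludes roughly the two voxels nearest an interface, and any voxel at
  least 3 FWHM deep is guaranteed above threshold.

### What the synthetic world does not show

Passing tests demonstrate correctness of the numerics and the *mechanism*
of boundary error and erosion, not in vivo fidelity. Real B1+ fields are
continuous across interfaces (only their curvature changes), anatomy is
convoluted rather than concentric, and real segmentations err. Three
consequences observed in this package's own experiments: the synthetic
boundary transients are net-positive for GM (driven by the large GM/CSF
field jump), so without erosion GM is biased *above* truth here whereas
in vivo it sits below; the clean geometric P > 0.99 masks already exclude
most of the WM boundary band, so raw-mask WM shows almost no boundary
inflation; and the in-plane kernel's ~10% through-slice deficit is the
dominant WM bias, as it is in vivo after erosion. The erosion experiment
therefore reproduces the variance-reduction and GM-accuracy effects of
boundary erosion on every seed, but not the in vivo bias directions.

## Experiment problem sizes and tolerances

- Ground-truth recovery: noiseless, full 3D kernel, masks eroded by
  radius 4 (= kernel half-width + 1, the smallest radius that clears the
  derivative footprint of every interface); per-tissue means recover the
  assigned values to better than 1% (asserted at 3%).
- Oracle equivalence: per-voxel `Im(lap B/B)/(mu0*omega)` within 2% of the
  closed form on plane-wave (max ~0.6%) and J0-cylinder (max ~0.3%)
  fields; preprocessing disabled since the check targets the kernel, and
  the J0 check runs at 1.5 mm spacing to keep the stencil's own O((kh)^2)
  truncation error well inside the band for CSF's large |k|.
- Boundary-erosion experiment: 5 seeds ("subjects") at SNR 50, 7x7
  kernel, threshold 0.99, disk radius 2 — the in vivo protocol settings.
- Noise robustness: 20 paired seeds on a homogeneous WM ellipsoid
  (64x64x12 grid); the 7x7 kernel's interior sigma-std (~0.24 S/m) beats
  3x3 (~1.05 S/m) on every seed.
- Degenerate inputs: empty foreground or an all-invalid result raises
  explicitly; zero-radius geometry yields an all-background phantom;
  radius-0 erosion and zero apodization/blur are exact identities.

## Known limitations

- No full-wave electromagnetic solver and no anatomical head model; the
  analytic fields are interface-discontinuous (see above).
- No phase wrapping/unwrapping; phases are synthesized unwrapped.
- No B1-magnitude mapping simulation, receive-profile correction,
  permittivity reconstruction, or motion/pulsation artifacts.
- The 0.5 mm slice gap of a real 2D protocol is not modelled; slices are
  treated as contiguous for the (optional) through-slice derivative.
- The exact coefficients of published "large" kernels vary by reference;
  the quadratic-fit construction here is the standard family member, not
  a bitwise match to any one implementation. Likewise the disk element is
  the exact Euclidean disk, which may differ from a toolbox's
  approximated disk by corner voxels.
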