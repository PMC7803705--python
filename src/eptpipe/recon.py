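"""Helmholtz-based conductivity reconstruction.

The chain mirrors a standard MR-EPT post-processing pipeline:

1. combine the two spin-echo phase maps (opposite readout polarities) to
   cancel odd eddy-current terms;
2. assemble the complex B1+ field under the half-transceive-phase
   assumption, ``B = |B| * exp(1j * phi_pm / 2)``;
3. suppress Gibbs ringing with a local subvoxel-shift method and apodize
   k-space with a Gaussian window (both per 2D slice);
4. apply a noise-robust second-derivative (Savitzky-Golay) kernel to get
   the Laplacian — in-plane 7x7 by default, optionally extended through
   slices — and map conductivity as

       sigma(r) = Im( lap(B1+) / B1+ ) / (mu0 * omega)      [S/m]

Voxels whose kernel footprint leaves the foreground, or whose magnitude is
below a floor, are flagged invalid rather than silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .datatypes import (
    MU0,
    ComplexField,
    ConductivityMap,
    GridMismatchError,
    PhaseVolume,
    VoxelGrid,
    larmor_omega,
)

__all__ = [
    "KernelSpec",
    "ReconParams",
    "EmptyReconstructionError",
    "combine_spin_echo_phases",
    "assemble_complex_b1",
    "gibbs_correct",
    "apodize_kspace",
    "second_derivative_stencil",
    "stencil_from_window",
    "build_kernel",
    "apply_laplacian",
    "reconstruct_conductivity",
]


class EmptyReconstructionError(ValueError):
    """No voxel survived the validity rules; the result would be empty."""


# ---------------------------------------------------------------------------
# phase handling
# ---------------------------------------------------------------------------

def combine_spin_echo_phases(phi1: PhaseVolume, phi2: PhaseVolume) -> PhaseVolume:
    """Average the two opposite-polarity spin-echo phase maps.

    Any phase term that is odd under readout-polarity reversal (the
    eddy-current ramp) cancels exactly; the transceive phase survives.
    """
    if phi1.grid.shape != phi2.grid.shape or phi1.grid.spacing_mm != phi2.grid.spacing_mm:
        raise GridMismatchError("spin-echo phase volumes are on different grids")
    if phi1.wrapped or phi2.wrapped:
        raise ValueError("phase combination requires unwrapped phase maps")
    return PhaseVolume(phi1.grid, 0.5 * (phi1.values + phi2.values), wrapped=False)


def assemble_complex_b1(
    magnitude: np.ndarray, transceive_phase: PhaseVolume
) -> ComplexField:
    """Build the complex B1+ field, approximating its phase as half the
    transceive phase."""
    magnitude = np.asarray(magnitude, dtype=float)
    if magnitude.shape != transceive_phase.grid.shape:
        raise GridMismatchError("magnitude shape does not match phase grid")
    if np.any(magnitude < 0):
        raise ValueError("B1+ magnitude must be non-negative")
    values = magnitude * np.exp(0.5j * transceive_phase.values)
    return ComplexField(grid=transceive_phase.grid, values=values)


# ---------------------------------------------------------------------------
# per-slice k-space conditioning
# ---------------------------------------------------------------------------

def _unring_axis(slab: np.ndarray, axis: int, n_shifts: int = 21) -> np.ndarray:
    """Subvoxel-shift Gibbs suppression along one axis of a real 2D array.

    Each line is resampled at ``n_shifts`` subvoxel shifts in [-0.5, 0.5]
    via Fourier interpolation; per voxel, the shift minimizing the local
    total variation (3-voxel window) is selected and the sampled value is
    shifted back to the voxel center with a first-order correction.
    Ringing oscillates at the Nyquist rate, so sampling between the
    oscillation extrema suppresses it; smooth signals are left untouched.
    """
    arr = np.moveaxis(slab, axis, 0)
    n = arr.shape[0]
    spec = np.fft.fft(arr, axis=0)
    freqs = np.fft.fftfreq(n)
    shifts = np.linspace(-0.5, 0.5, n_shifts)
    # shifted[s, i, :] = line(i + shifts[s]) by the Fourier shift theorem
    ramp = np.exp(2j * np.pi * freqs[None, :, None] * shifts[:, None, None])
    shifted = np.fft.ifft(spec[None, :, :] * ramp, axis=1).real

    tv = np.abs(np.roll(shifted, -1, axis=1) - shifted) + np.abs(
        shifted - np.roll(shifted, 1, axis=1)
    )
    best = np.argmin(tv, axis=0)  # (n, m)
    picked = np.take_along_axis(shifted, best[None, :, :], axis=0)[0]
    s_best = shifts[best]
    # Taylor-unshift the sampled value back to the voxel center; the
    # second-order term matters because downstream Laplacians measure
    # exactly the curvature an O(s**2) residual would corrupt.
    slope = 0.5 * (np.roll(picked, -1, axis=0) - np.roll(picked, 1, axis=0))
    curv = np.roll(picked, -1, axis=0) - 2.0 * picked + np.roll(picked, 1, axis=0)
    corrected = picked - s_best * slope + 0.5 * s_best**2 * curv
    # Correct only where the shift genuinely found a less oscillatory
    # sampling (Gibbs ringing); smooth voxels keep their original value,
    # so ringing-free data pass through untouched.
    i0 = n_shifts // 2  # shift 0 (n_shifts is odd)
    tv_best = np.take_along_axis(tv, best[None, :, :], axis=0)[0]
    oscillatory = tv_best < 0.8 * tv[i0]
    return np.moveaxis(np.where(oscillatory, corrected, arr), 0, axis)


def gibbs_correct(fieldvol: ComplexField, n_shifts: int = 21) -> ComplexField:
    """Suppress Gibbs ringing slice by slice, independently on the real and
    imaginary channels, along both in-plane axes."""
    values = fieldvol.values.copy()
    for iz in range(fieldvol.grid.shape[2]):
        for channel in (np.real, np.imag):
            sl = np.ascontiguousarray(channel(values[:, :, iz]))
            sl = _unring_axis(sl, axis=0, n_shifts=n_shifts)
            sl = _unring_axis(sl, axis=1, n_shifts=n_shifts)
            if channel is np.real:
                real_part = sl
            else:
                imag_part = sl
        values[:, :, iz] = real_part + 1j * imag_part
    return ComplexField(grid=fieldvol.grid, values=values)


def apodize_kspace(fieldvol: ComplexField, apodization_sigma: float) -> ComplexField:
    """Multiply each slice's 2D spectrum by a centered Gaussian window.

    ``apodization_sigma`` is the window standard deviation as a fraction of
    the Nyquist radius; the window equals 1 at k = 0, so mean signal levels
    are preserved while high spatial frequencies (noise, residual ringing)
    are attenuated.
    """
    if apodization_sigma <= 0:
        return ComplexField(grid=fieldvol.grid, values=fieldvol.values.copy())
    nx, ny, nz = fieldvol.grid.shape
    ux = np.fft.fftfreq(nx)[:, None]  # cycles/sample, Nyquist at 0.5
    uy = np.fft.fftfreq(ny)[None, :]
    sigma_u = apodization_sigma * 0.5
    window = np.exp(-(ux**2 + uy**2) / (2.0 * sigma_u**2))
    values = np.empty_like(fieldvol.values)
    for iz in range(nz):
        spec = np.fft.fft2(fieldvol.values[:, :, iz])
        values[:, :, iz] = np.fft.ifft2(spec * window)
    return ComplexField(grid=fieldvol.grid, values=values)


# ---------------------------------------------------------------------------
# noise-robust derivative kernels
# ---------------------------------------------------------------------------

def second_derivative_stencil(half_width: int) -> np.ndarray:
    """1D second-derivative weights from a least-squares quadratic fit over
    ``2*half_width + 1`` points at unit spacing (Savitzky-Golay order 2).

    Closed form: with offsets ``j`` and moments ``S2 = sum(j**2)``,
    ``S4 = sum(j**4)``, ``N`` points, the weights are
    ``w_j = 2 * (j**2 - S2/N) / (S4 - S2**2/N)``.  They reproduce the
    exact second derivative of any quadratic and annihilate constants and
    linears; for ``half_width == 1`` they reduce to ``(1, -2, 1)``.
    """
    if half_width < 1:
        raise ValueError("second-derivative stencil needs half_width >= 1")
    j = np.arange(-half_width, half_width + 1, dtype=float)
    n = j.size
    s2 = np.sum(j**2)
    s4 = np.sum(j**4)
    w = 2.0 * (j**2 - s2 / n) / (s4 - s2**2 / n)
    return w - w.mean()  # zero-sum to the last bit: constants map to 0


def stencil_from_window(window: int) -> np.ndarray:
    """Second-derivative stencil for an odd window length (voxels)."""
    if window % 2 == 0 or window < 3:
        raise ValueError(f"derivative window must be odd and >= 3, got {window}")
    return second_derivative_stencil(window // 2)


@dataclass(frozen=True)
class KernelSpec:
    """Noise-robust Laplacian kernel specification.

    ``mode`` selects in-plane-only (2D) or full (3D) second derivatives;
    ``half_widths`` gives the kernel half-extent per axis in voxels.  The
    defaults reproduce the large in-plane kernel (7 x 7) and its 3D
    extension (7 x 7 x 3).  Along each derivative axis the weights are the
    Savitzky-Golay quadratic-fit stencil; across the remaining footprint
    axes the derivative is averaged uniformly, which is what makes the
    large kernel noise-robust while keeping it exact on quadratics.
    """

    mode: str = "2d"
    half_widths: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("2d", "3d"):
            raise ValueError(f"kernel mode must be '2d' or '3d', got {self.mode!r}")
        hw = self.half_widths
        if hw is None:
            hw = (3, 3, 0) if self.mode == "2d" else (3, 3, 1)
        hw = tuple(int(h) for h in hw)
        if hw[0] < 1 or hw[1] < 1:
            raise ValueError("in-plane half-widths must be >= 1")
        if self.mode == "3d" and hw[2] < 1:
            raise ValueError("3D kernel needs z half-width >= 1")
        if self.mode == "2d" and hw[2] != 0:
            raise ValueError("2D kernel must have z half-width 0")
        object.__setattr__(self, "half_widths", hw)

    @property
    def derivative_axes(self) -> tuple[int, ...]:
        return (0, 1) if self.mode == "2d" else (0, 1, 2)

    @property
    def footprint_shape(self) -> tuple[int, int, int]:
        return tuple(2 * h + 1 for h in self.half_widths)


def build_kernel(spec: KernelSpec, spacing_mm: tuple[float, float, float]) -> np.ndarray:
    """Assemble the 3D Laplacian convolution weights for a kernel spec.

    The result sums, over the derivative axes, the separable product of a
    1D second-derivative stencil (scaled by 1/spacing**2 in metres) along
    that axis and uniform averaging along the other footprint axes.
    """
    shape = spec.footprint_shape
    spacing_m = [s * 1e-3 for s in spacing_mm]
    kernel = np.zeros(shape, dtype=float)
    for axis in spec.derivative_axes:
        factors = []
        for a in range(3):
            if a == axis:
                factors.append(
                    second_derivative_stencil(spec.half_widths[a]) / spacing_m[a] ** 2
                )
            else:
                factors.append(np.full(shape[a], 1.0 / shape[a]))
        kernel += (
            factors[0][:, None, None] * factors[1][None, :, None] * factors[2][None, None, :]
        )
    return kernel


def apply_laplacian(
    fieldvol: ComplexField, spec: KernelSpec, foreground: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve the field with the Laplacian kernel and derive validity.

    A voxel is valid only when the *entire* kernel footprint lies inside
    the foreground mask (excluding image edges and air).  Footprints that
    straddle tissue-tissue interfaces are deliberately kept: boundary
    errors are the phenomenon under study, not an input defect.
    """
    foreground = np.asarray(foreground, dtype=bool)
    if foreground.shape != fieldvol.grid.shape:
        raise GridMismatchError("foreground mask shape does not match field")
    shape = spec.footprint_shape
    if any(k > n for k, n in zip(shape, fieldvol.grid.shape)):
        raise ValueError(
            f"kernel footprint {shape} larger than volume {fieldvol.grid.shape}"
        )
    kernel = build_kernel(spec, fieldvol.grid.spacing_mm)
    lap_re = ndimage.convolve(fieldvol.values.real, kernel, mode="constant", cval=0.0)
    lap_im = ndimage.convolve(fieldvol.values.imag, kernel, mode="constant", cval=0.0)
    validity = ndimage.binary_erosion(
        foreground, structure=np.ones(shape, dtype=bool), border_value=0
    )
    return lap_re + 1j * lap_im, validity


# ---------------------------------------------------------------------------
# conductivity mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReconParams:
    """Reconstruction parameters.

    ``magnitude_floor`` is the fraction of the maximum foreground |B1+|
    below which voxels are marked invalid (division guard near field
    nulls); ``apodization_sigma`` <= 0 disables apodization.
    """

    omega: float = field(default_factory=larmor_omega)
    mu0: float = MU0
    kernel: KernelSpec = field(default_factory=KernelSpec)
    apodization_sigma: float = 0.4
    gibbs_correction: bool = True
    magnitude_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError("omega must be positive")
        if not math.isclose(self.mu0, MU0, rel_tol=1e-12):
            raise ValueError("mu0 must be the free-space permeability")
        if not 0 < self.magnitude_floor < 1:
            raise ValueError("magnitude_floor must be in (0, 1)")

    def with_kernel(self, kernel: KernelSpec) -> "ReconParams":
        return replace(self, kernel=kernel)


def reconstruct_conductivity(
    fieldvol: ComplexField, params: ReconParams, foreground: np.ndarray
) -> ConductivityMap:
    """Map conductivity from a complex B1+ field.

    Runs the configured per-slice conditioning (Gibbs correction, then
    Gaussian apodization), applies the noise-robust Laplacian, and
    evaluates ``sigma = Im(lap(B)/B) / (mu0 * omega)`` wherever the kernel
    footprint stays inside the foreground and |B| is above the magnitude
    floor.  Invalid voxels are flagged, never silently zeroed.
    """
    work = fieldvol
    if params.gibbs_correction:
        work = gibbs_correct(work)
    if params.apodization_sigma > 0:
        work = apodize_kspace(work, params.apodization_sigma)

    lap, validity = apply_laplacian(work, params.kernel, foreground)
    mag = np.abs(work.values)
    fg_max = mag[np.asarray(foreground, dtype=bool)].max(initial=0.0)
    validity = validity & (mag >= params.magnitude_floor * fg_max)
    if not np.any(validity):
        raise EmptyReconstructionError(
            "no voxel passed the kernel-footprint and magnitude-floor checks"
        )
    sigma = np.zeros(fieldvol.grid.shape, dtype=float)
    ratio = lap[validity] / work.values[validity]
    sigma[validity] = ratio.imag / (params.mu0 * params.omega)
    return ConductivityMap(grid=fieldvol.grid, values=sigma, validity=validity)
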