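"""Synthetic phantoms, Helmholtz-consistent B1+ fields, and the emulated
MR acquisition chain.

The phantom is a set of nested ellipsoidal shells (CSF shell, GM shell, WM
core by default) carrying literature electrical properties at 128 MHz.
Fields are closed-form solutions of the Helmholtz equation evaluated
piecewise per tissue, so ``Im(lap(B)/B) = omega*mu0*sigma`` holds exactly
inside every homogeneous compartment while the field is discontinuous at
tissue interfaces — deliberately reproducing the boundary-error phenomenon
that large derivative kernels suffer from.  The acquisition emulator adds
the corruptions a 2D spin-echo protocol exhibits: per-slice k-space
truncation (Gibbs ringing), complex Gaussian noise at a prescribed SNR,
opposite-polarity eddy-current phase ramps, and random per-slice phase
offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import jv

from .datatypes import (
    AcquisitionParams,
    ComplexField,
    ConfigurationError,
    GeometryError,
    LABEL_CSF,
    LABEL_GM,
    LABEL_WM,
    LITERATURE_PROPERTIES_128MHZ,
    PhantomModel,
    PhaseVolume,
    ProbabilityMaps,
    TissueProperties,
    VoxelGrid,
    complex_wavenumber,
    larmor_omega,
)

__all__ = [
    "ShellSpec",
    "NestedEllipsoidGeometry",
    "default_brain_geometry",
    "generate_label_phantom",
    "assign_tissue_properties",
    "generate_planewave_field",
    "generate_j0_cylinder_field",
    "emulate_acquisition",
    "split_transceive_phases",
    "apply_slice_phase_offsets",
    "generate_probability_maps",
]


@dataclass(frozen=True)
class ShellSpec:
    """One shell of the nested-ellipsoid phantom.

    ``thickness_mm`` is subtracted from every semi-axis to obtain the next
    (inner) ellipsoid; ``None`` marks the innermost shell, which fills the
    remaining core.
    """

    label: int
    thickness_mm: float | None = None


@dataclass(frozen=True)
class NestedEllipsoidGeometry:
    """Nested-ellipsoid phantom geometry, ordered outermost to innermost."""

    semi_axes_mm: tuple[float, float, float]
    shells: tuple[ShellSpec, ...]
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shells) == 0:
            raise GeometryError("geometry needs at least one shell")
        for s in self.shells[:-1]:
            if s.thickness_mm is None:
                raise GeometryError("only the innermost shell may omit thickness")
        object.__setattr__(self, "shells", tuple(self.shells))


def default_brain_geometry(
    csf_thickness_mm: float = 12.5, gm_thickness_mm: float = 20.0
) -> NestedEllipsoidGeometry:
    """Three-compartment brain-like phantom: CSF shell, GM shell, WM core.

    The outer envelope (95 x 105 x 42.5 mm semi-axes) fills most of a
    240 x 240 x 90 mm field of view.  The CSF shell is thin by default,
    mirroring the limited spatial extension of CSF in vivo; its thickness
    is configurable so that experiments needing eroded CSF statistics can
    use a thicker shell.
    """
    return NestedEllipsoidGeometry(
        semi_axes_mm=(95.0, 105.0, 42.5),
        shells=(
            ShellSpec(LABEL_CSF, csf_thickness_mm),
            ShellSpec(LABEL_GM, gm_thickness_mm),
            ShellSpec(LABEL_WM, None),
        ),
    )


def generate_label_phantom(
    grid: VoxelGrid, geometry: NestedEllipsoidGeometry
) -> PhantomModel:
    """Rasterize a nested-ellipsoid geometry into an integer label volume.

    A voxel belongs to the outermost ellipsoid that contains its center;
    inner shells overwrite outer ones, so the result is concentric.
    Degenerate (zero or negative) semi-axes simply produce no voxels for
    that shell and everything inside it.
    """
    semi = np.asarray(geometry.semi_axes_mm, dtype=float)
    if np.any(semi > 0.5 * np.asarray(grid.shape) * np.asarray(grid.spacing_mm) + 1e-9):
        raise GeometryError(
            f"outer semi-axes {tuple(semi)} mm exceed half the grid extent"
        )
    x, y, z = grid.coords_mm()
    cx, cy, cz = geometry.center_mm
    labels = np.zeros(grid.shape, dtype=np.int16)

    current = semi.copy()
    for shell in geometry.shells:
        if np.all(current > 0):
            rho2 = (
                ((x - cx) / current[0]) ** 2
                + ((y - cy) / current[1]) ** 2
                + ((z - cz) / current[2]) ** 2
            )
            labels[rho2 <= 1.0] = shell.label
        if shell.thickness_mm is not None:
            if shell.thickness_mm < 0:
                raise GeometryError("shell thickness must be >= 0")
            current = current - shell.thickness_mm
    return PhantomModel(grid=grid, labels=labels)


def assign_tissue_properties(
    phantom: PhantomModel,
    frequency_hz: float = 128e6,
    overrides: dict[int, TissueProperties] | None = None,
) -> PhantomModel:
    """Attach per-label electrical properties (defaults: literature ex vivo
    values at 128 MHz — WM 0.34, GM 0.59, CSF 2.14 S/m).

    ``overrides`` replaces or adds entries per label.  Every nonzero label
    present in the volume must end up with properties.
    """
    if not frequency_hz > 0:
        raise ConfigurationError("frequency must be positive")
    props = dict(LITERATURE_PROPERTIES_128MHZ)
    if overrides:
        props.update(overrides)
    for lab in phantom.present_labels():
        if lab not in props:
            raise ConfigurationError(
                f"label {lab} present in phantom but has no tissue properties"
            )
    phantom.properties = {lab: props[lab] for lab in phantom.present_labels()}
    return phantom


def _per_label_wavenumbers(phantom: PhantomModel, omega: float) -> dict[int, complex]:
    return {
        lab: complex_wavenumber(p.sigma, p.eps_r, omega)
        for lab, p in phantom.properties.items()
    }


def generate_planewave_field(
    phantom: PhantomModel,
    omega: float | None = None,
    direction: tuple[float, float, float] = (1.0, 2.0, 0.745),
) -> ComplexField:
    """Piecewise plane wave ``B(r) = exp(-1j * k_tissue * (n . r))``.

    Inside each homogeneous compartment the field satisfies the Helmholtz
    equation exactly (``lap(B)/B = -k**2``); across interfaces it jumps,
    because each region's wavenumber is applied to the same global phase
    argument.  Background (air) voxels carry no MR signal and are set to 0.
    """
    omega = larmor_omega() if omega is None else omega
    n = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("direction must be a nonzero vector")
    n = n / norm
    x, y, z = phantom.grid.coords_m()
    proj = n[0] * x + n[1] * y + n[2] * z  # metres, broadcast to grid shape
    proj = np.broadcast_to(proj, phantom.grid.shape)

    values = np.zeros(phantom.grid.shape, dtype=np.complex128)
    for lab, k in _per_label_wavenumbers(phantom, omega).items():
        sel = phantom.labels == lab
        values[sel] = np.exp(-1j * k * proj[sel])
    return ComplexField(grid=phantom.grid, values=values)


def generate_j0_cylinder_field(
    radius_m: float,
    sigma: float,
    eps_r: float,
    omega: float | None = None,
    grid: VoxelGrid | None = None,
) -> ComplexField:
    """Quadrature-excitation field of an infinite homogeneous cylinder:
    ``B1+(rho) = J0(k * rho)``, z-independent.

    This is the canonical analytic birdcage-coil solution for a homogeneous
    lossy cylinder; inside the cylinder ``lap(B)/B = -k**2`` in the
    continuum, with zero through-slice derivatives.
    """
    omega = larmor_omega() if omega is None else omega
    if grid is None:
        grid = VoxelGrid(shape=(96, 96, 8))
    x, y, _ = grid.coords_m()
    rho = np.broadcast_to(np.sqrt(x**2 + y**2), grid.shape)
    half_extent = (
        min(grid.shape[0] * grid.spacing_m[0], grid.shape[1] * grid.spacing_m[1]) / 2.0
    )
    if radius_m > half_extent:
        raise GeometryError(
            f"cylinder radius {radius_m} m exceeds in-plane grid half-extent "
            f"{half_extent} m"
        )
    k = complex_wavenumber(sigma, eps_r, omega)
    values = np.where(rho <= radius_m, jv(0, k * rho), 0.0)
    return ComplexField(grid=grid, values=np.ascontiguousarray(values))


def _truncate_kspace_slice(sl: np.ndarray, matrix: tuple[int, int]) -> np.ndarray:
    """Zero all but the central ``matrix`` region of a slice's 2D spectrum."""
    nx, ny = sl.shape
    mx, my = matrix
    spec = np.fft.fftshift(np.fft.fft2(sl))
    keep = np.zeros_like(spec, dtype=bool)
    x0 = (nx - mx) // 2
    y0 = (ny - my) // 2
    keep[x0 : x0 + mx, y0 : y0 + my] = True
    spec[~keep] = 0.0
    return np.fft.ifft2(np.fft.ifftshift(spec))


def emulate_acquisition(
    fieldvol: ComplexField,
    params: AcquisitionParams,
    foreground: np.ndarray | None = None,
) -> ComplexField:
    """Apply the acquisition chain: per-slice 2D k-space truncation
    (zero-filled back to the grid), then additive complex Gaussian noise.

    The per-channel noise standard deviation is defined as
    ``mean(|B1+|) over the foreground / snr`` — the SNR convention common
    in B1-mapping work.  ``foreground`` defaults to voxels with nonzero
    magnitude.  Identical inputs and seed give bitwise-identical output.
    """
    values = fieldvol.values.copy()
    nx, ny, nz = fieldvol.grid.shape

    if params.acquisition_matrix is not None:
        mx, my = params.acquisition_matrix
        if mx > nx or my > ny:
            raise ConfigurationError(
                f"acquisition matrix {params.acquisition_matrix} exceeds grid "
                f"in-plane dims {(nx, ny)}"
            )
        for iz in range(nz):
            values[:, :, iz] = _truncate_kspace_slice(values[:, :, iz], (mx, my))

    if params.snr is not None and np.isfinite(params.snr):
        if foreground is None:
            foreground = np.abs(fieldvol.values) > 0
        if not np.any(foreground):
            raise ConfigurationError("cannot calibrate noise: empty foreground")
        noise_std = float(np.mean(np.abs(values[foreground]))) / params.snr
        rng = np.random.default_rng(params.seed)
        values = values + noise_std * (
            rng.standard_normal(values.shape) + 1j * rng.standard_normal(values.shape)
        )
    return ComplexField(grid=fieldvol.grid, values=values)


def split_transceive_phases(
    fieldvol: ComplexField, params: AcquisitionParams
) -> tuple[PhaseVolume, PhaseVolume]:
    """Synthesize the two spin-echo phase maps acquired with opposite
    readout gradient polarities.

    The transceive phase is ``2 * arg(B1+)`` (the synthetic world makes the
    half-transceive-phase assumption exact), and the eddy-current
    contribution is a phase ramp along the readout axis (axis 0) that flips
    sign with gradient polarity::

        phi1 = 2*arg(B) + g*i_x,   phi2 = 2*arg(B) - g*i_x

    so the average of the pair cancels the ramp identically.
    """
    transceive = 2.0 * np.angle(fieldvol.values)
    ix = np.arange(fieldvol.grid.shape[0], dtype=float)[:, None, None]
    eddy = params.eddy_gradient * ix
    phi1 = PhaseVolume(fieldvol.grid, transceive + eddy, wrapped=False)
    phi2 = PhaseVolume(fieldvol.grid, transceive - eddy, wrapped=False)
    return phi1, phi2


def apply_slice_phase_offsets(
    phase: PhaseVolume, params: AcquisitionParams, stream: int = 0
) -> PhaseVolume:
    """Add one random constant phase offset per z-slice, drawn uniformly
    from ``[-slice_offset_scale, +slice_offset_scale]``.

    2D multi-slice sequences acquire each slice as an independent
    excitation, so slice-to-slice phase references are arbitrary; this is
    the corruption that forbids through-slice derivatives in vivo.
    ``stream`` decorrelates the two spin-echo acquisitions while keeping
    everything reproducible from ``params.seed``.
    """
    rng = np.random.default_rng((int(params.seed), int(stream)))
    nz = phase.grid.shape[2]
    offsets = rng.uniform(
        -params.slice_offset_scale, params.slice_offset_scale, size=nz
    )
    return PhaseVolume(
        phase.grid, phase.values + offsets[None, None, :], wrapped=False
    )


def generate_probability_maps(
    phantom: PhantomModel, blur_fwhm_mm: float = 5.0
) -> ProbabilityMaps:
    """Soft tissue-membership maps standing in for an SPM-style segmentation.

    Per-class indicator volumes (including background) are smoothed with a
    Gaussian of the given FWHM and renormalized voxelwise to sum to one;
    the blur creates realistic partial-volume probabilities below 1 near
    interfaces.  The default FWHM of two voxels (5 mm) models the
    partial-volume transition a segmentation of 2.5 mm data exhibits, and
    makes the P > 0.99 threshold exclude roughly the two voxels nearest an
    interface (a voxel at >= 3 FWHM from every interface always has
    P > 0.99).
    """
    if blur_fwhm_mm < 0:
        raise ValueError("blur FWHM must be >= 0")
    all_labels = [0] + phantom.present_labels()
    smoothed: dict[int, np.ndarray] = {}
    sigma_vox = [
        blur_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / s
        for s in phantom.grid.spacing_mm
    ]
    for lab in all_labels:
        ind = (phantom.labels == lab).astype(float)
        smoothed[lab] = gaussian_filter(ind, sigma=sigma_vox) if blur_fwhm_mm > 0 else ind
    total = sum(smoothed.values())
    total[total == 0] = 1.0
    maps = {lab: smoothed[lab] / total for lab in all_labels if lab != 0}
    return ProbabilityMaps(grid=phantom.grid, maps=maps)
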