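"""Core containers and physical constants shared by all pipeline stages.

Volumes live on a :class:`VoxelGrid` with voxel-centered, axis-aligned
coordinates.  Spacing is stored in millimetres (the unit NIfTI headers and
scanner protocols use); every physical computation converts to metres
internally, so the Helmholtz identity ``Im(lap(B)/B) = omega * mu0 * sigma``
holds in SI units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: Free-space permeability [H/m].
MU0 = 4e-7 * np.pi
#: Free-space permittivity [F/m].
EPS0 = 8.8541878128e-12
#: Proton Larmor frequency at 3 T [Hz].
DEFAULT_FREQUENCY_HZ = 128e6


def larmor_omega(frequency_hz: float = DEFAULT_FREQUENCY_HZ) -> float:
    """Angular frequency [rad/s] for a given RF frequency."""
    return 2.0 * np.pi * frequency_hz


def complex_wavenumber(sigma: float, eps_r: float, omega: float) -> complex:
    """Complex wavenumber ``k`` with ``k**2 = omega**2*mu0*eps - 1j*omega*mu0*sigma``.

    The sign convention is fixed so that a field ``B = exp(-1j*k*(n.r))``
    satisfies ``lap(B)/B = -k**2`` and therefore
    ``Im(lap(B)/B) = omega*mu0*sigma >= 0``: conductivity maps come out
    positive without any downstream sign flip.  The principal square root
    puts ``Re(k) > 0`` and ``Im(k) <= 0`` (decay along +n for lossy media).
    """
    k2 = omega**2 * MU0 * EPS0 * eps_r - 1j * omega * MU0 * sigma
    return complex(np.sqrt(k2))


class GeometryError(ValueError):
    """Requested phantom geometry does not fit the voxel grid."""


class ConfigurationError(ValueError):
    """Inconsistent or incomplete configuration."""


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice with physical spacing.

    Parameters
    ----------
    shape
        Number of voxels per axis ``(nx, ny, nz)``; all >= 1.
    spacing_mm
        Voxel edge length per axis in millimetres; all > 0.
    origin_mm
        Physical coordinate of voxel ``(0, 0, 0)``.  Defaults to placing
        the grid center at the physical origin, which keeps synthetic-field
        magnitudes O(1) near the middle of the volume.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"grid spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))

    @property
    def spacing_m(self) -> tuple[float, float, float]:
        return tuple(s * 1e-3 for s in self.spacing_mm)

    @property
    def origin(self) -> tuple[float, float, float]:
        if self.origin_mm is not None:
            return tuple(float(o) for o in self.origin_mm)
        return tuple(-(n - 1) / 2.0 * s for n, s in zip(self.shape, self.spacing_mm))

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates in millimetres."""
        o = self.origin
        return tuple(
            o[a] + np.arange(self.shape[a]) * self.spacing_mm[a] for a in range(3)
        )

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable voxel-center coordinate volumes in millimetres."""
        ax = self.axes_mm()
        return np.meshgrid(*ax, indexing="ij", sparse=True)

    def coords_m(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(c * 1e-3 for c in self.coords_mm())


def _require_same_grid(a: VoxelGrid, b: VoxelGrid) -> None:
    if a.shape != b.shape or a.spacing_mm != b.spacing_mm:
        raise GridMismatchError(f"grids differ: {a} vs {b}")


@dataclass(frozen=True)
class TissueProperties:
    """Electrical properties of one tissue class."""

    name: str
    sigma: float  # conductivity [S/m]
    eps_r: float  # relative permittivity

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"conductivity must be >= 0, got {self.sigma}")
        if self.eps_r < 1:
            raise ValueError(f"relative permittivity must be >= 1, got {self.eps_r}")


#: Canonical label assignment used throughout the package.
LABEL_BACKGROUND, LABEL_WM, LABEL_GM, LABEL_CSF = 0, 1, 2, 3

#: Ex vivo literature electrical properties of brain tissue at 128 MHz
#: (dielectric-probe measurements on excised tissue).  Conductivities in S/m.
LITERATURE_PROPERTIES_128MHZ: Mapping[int, TissueProperties] = {
    LABEL_WM: TissueProperties("WM", sigma=0.34, eps_r=52.5),
    LABEL_GM: TissueProperties("GM", sigma=0.59, eps_r=73.5),
    LABEL_CSF: TissueProperties("CSF", sigma=2.14, eps_r=84.0),
}

LABEL_NAMES: Mapping[int, str] = {
    LABEL_BACKGROUND: "background",
    LABEL_WM: "WM",
    LABEL_GM: "GM",
    LABEL_CSF: "CSF",
}


@dataclass
class PhantomModel:
    """Ground-truth piecewise-constant phantom: labels plus per-label properties."""

    grid: VoxelGrid
    labels: np.ndarray  # integer volume, 0 = background/air
    properties: dict[int, TissueProperties] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise GridMismatchError("label volume shape does not match grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0

    def present_labels(self) -> list[int]:
        return sorted(int(l) for l in np.unique(self.labels) if l != 0)

    def sigma_map(self) -> np.ndarray:
        """Ground-truth conductivity volume [S/m]; background is 0."""
        out = np.zeros(self.grid.shape, dtype=float)
        for lab in self.present_labels():
            out[self.labels == lab] = self.properties[lab].sigma
        return out


@dataclass
class ComplexField:
    """Complex B1+ samples on a voxel grid (arbitrary field units)."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError("field shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)


@dataclass
class PhaseVolume:
    """Phase samples in radians; ``wrapped`` marks values confined to (-pi, pi]."""

    grid: VoxelGrid
    values: np.ndarray
    wrapped: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError("phase shape does not match grid")
        if self.wrapped and (self.values.min() <= -np.pi or self.values.max() > np.pi):
            raise ValueError("wrapped phase must lie in (-pi, pi]")


@dataclass
class ProbabilityMaps:
    """Per-tissue membership probabilities (the synthetic analogue of a
    soft segmentation); per-voxel sum over tissues is <= 1, the remainder
    being background."""

    grid: VoxelGrid
    maps: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        for lab, p in self.maps.items():
            p = np.asarray(p, dtype=float)
            if p.shape != self.grid.shape:
                raise GridMismatchError(f"probability map {lab} shape mismatch")
            if p.min() < -1e-9 or p.max() > 1 + 1e-9:
                raise ValueError(f"probabilities for label {lab} outside [0, 1]")
            self.maps[lab] = np.clip(p, 0.0, 1.0)
        total = sum(self.maps.values())
        if np.any(total > 1 + 1e-6):
            raise ValueError("per-voxel tissue probabilities sum above 1")


@dataclass
class TissueMask:
    """Boolean membership volume for one tissue, with provenance tracking."""

    grid: VoxelGrid
    label: int
    mask: np.ndarray
    provenance: str = "raw-threshold"  # or "eroded"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise GridMismatchError("mask shape does not match grid")

    @property
    def name(self) -> str:
        return LABEL_NAMES.get(self.label, f"label{self.label}")

    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class ConductivityMap:
    """Reconstructed conductivity [S/m] with an explicit validity mask.

    ``values`` are meaningful only where ``validity`` is True; invalid
    voxels hold 0 but must never enter statistics.
    """

    grid: VoxelGrid
    values: np.ndarray
    validity: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.values.shape != self.grid.shape or self.validity.shape != self.grid.shape:
            raise GridMismatchError("conductivity map shape does not match grid")

    def valid_values(self, where: np.ndarray | None = None) -> np.ndarray:
        sel = self.validity if where is None else (self.validity & where)
        return self.values[sel]


@dataclass(frozen=True)
class AcquisitionParams:
    """Knobs of the emulated MR acquisition chain.

    ``snr`` is the ratio of the mean foreground |B1+| to the per-channel
    Gaussian noise standard deviation (``None`` disables noise).
    ``acquisition_matrix`` is the retained central k-space size per slice;
    ``None`` keeps the full matrix (no Gibbs truncation).
    """

    snr: float | None = 50.0
    seed: int = 0
    eddy_gradient: float = 0.01  # rad per voxel along the readout axis
    slice_offset_scale: float = np.pi  # rad; uniform per-slice offsets in [-s, s]
    acquisition_matrix: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.snr is not None and not self.snr > 0:
            raise ValueError("snr must be positive or None")
        if self.slice_offset_scale < 0:
            raise ValueError("slice_offset_scale must be >= 0")
        if self.acquisition_matrix is not None:
            object.__setattr__(
                self, "acquisition_matrix", tuple(int(m) for m in self.acquisition_matrix)
            )

    def with_seed(self, seed: int) -> "AcquisitionParams":
        return replace(self, seed=int(seed))
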