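"""Configuration objects for phantom synthesis, statistics, and the
end-to-end pipeline, with YAML/JSON-friendly (de)serialization.

A :class:`PipelineConfig` plus the package version determines every output
bit for bit: all randomness flows from the explicit seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .datatypes import AcquisitionParams, ConfigurationError, VoxelGrid, larmor_omega
from .phantom import NestedEllipsoidGeometry, default_brain_geometry
from .recon import KernelSpec, ReconParams


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom geometry and field-synthesis settings."""

    shape: tuple[int, int, int] = (96, 96, 36)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    semi_axes_mm: tuple[float, float, float] = (95.0, 105.0, 42.5)
    csf_thickness_mm: float = 12.5
    gm_thickness_mm: float = 20.0
    blur_fwhm_mm: float = 5.0
    frequency_hz: float = 128e6
    field_direction: tuple[float, float, float] = (1.0, 2.0, 0.745)

    def grid(self) -> VoxelGrid:
        return VoxelGrid(shape=self.shape, spacing_mm=self.spacing_mm)

    def geometry(self) -> NestedEllipsoidGeometry:
        geom = default_brain_geometry(self.csf_thickness_mm, self.gm_thickness_mm)
        return NestedEllipsoidGeometry(
            semi_axes_mm=self.semi_axes_mm, shells=geom.shells
        )

    @property
    def omega(self) -> float:
        return larmor_omega(self.frequency_hz)


@dataclass(frozen=True)
class StatsConfig:
    """ROI-statistics settings: probability threshold, erosion radius, and
    the standard-deviation convention (population by default)."""

    probability_threshold: float = 0.99
    erosion_radius: int = 2
    population_std: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    recon: ReconParams = field(default_factory=ReconParams)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = {
            "phantom": asdict(self.phantom),
            "acquisition": asdict(self.acquisition),
            "recon": {
                "frequency_hz": self.recon.omega / (2.0 * 3.141592653589793),
                "kernel_mode": self.recon.kernel.mode,
                "kernel_half_widths": list(self.recon.kernel.half_widths),
                "apodization_sigma": self.recon.apodization_sigma,
                "gibbs_correction": self.recon.gibbs_correction,
                "magnitude_floor": self.recon.magnitude_floor,
            },
            "stats": asdict(self.stats),
            "seed": self.seed,
        }
        d["phantom"]["shape"] = list(self.phantom.shape)
        d["phantom"]["spacing_mm"] = list(self.phantom.spacing_mm)
        d["phantom"]["semi_axes_mm"] = list(self.phantom.semi_axes_mm)
        d["phantom"]["field_direction"] = list(self.phantom.field_direction)
        acq = d["acquisition"]
        if acq["acquisition_matrix"] is not None:
            acq["acquisition_matrix"] = list(acq["acquisition_matrix"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        try:
            ph = dict(d.get("phantom", {}))
            for key in ("shape", "spacing_mm", "semi_axes_mm", "field_direction"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            phantom = PhantomConfig(**ph)

            ac = dict(d.get("acquisition", {}))
            if ac.get("acquisition_matrix") is not None:
                ac["acquisition_matrix"] = tuple(ac["acquisition_matrix"])
            acquisition = AcquisitionParams(**ac)

            rc = dict(d.get("recon", {}))
            freq = rc.pop("frequency_hz", phantom.frequency_hz)
            kernel = KernelSpec(
                mode=rc.pop("kernel_mode", "2d"),
                half_widths=(
                    tuple(rc.pop("kernel_half_widths"))
                    if "kernel_half_widths" in rc
                    else None
                ),
            )
            recon = ReconParams(omega=larmor_omega(freq), kernel=kernel, **rc)

            stats = StatsConfig(**d.get("stats", {}))
            seed = int(d.get("seed", 0))
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid pipeline configuration: {exc}") from exc
        return cls(
            phantom=phantom, acquisition=acquisition, recon=recon, stats=stats, seed=seed
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
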