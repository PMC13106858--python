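"""Run configuration, units, and default gene panels.

All public coordinates in this package are micrometres; pixels appear only
at I/O boundaries, converted through :class:`PixelScale`.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import yaml

log = logging.getLogger("plaqueniche")

#: Zone radius separating "plaque adjacent" from "outside", in µm.
#: 69 µm corresponds to 500 px on rendered Molecular Cartography slides.
DEFAULT_ZONE_RADIUS_UM = 69.0

#: Rendered-slide pixel size implied by the 69 µm == 500 px equivalence.
DEFAULT_MICRONS_PER_PIXEL = 69.0 / 500.0  # 0.138 µm/px


@dataclasses.dataclass(frozen=True)
class PixelScale:
    """Isotropic pixel size of a rendered image, in µm per pixel."""

    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ValueError(
                f"microns_per_pixel must be > 0, got {self.microns_per_pixel}"
            )

    def to_um(self, px):
        return px * self.microns_per_pixel

    def to_px(self, um):
        return um / self.microns_per_pixel

    @property
    def pixel_area_um2(self) -> float:
        return self.microns_per_pixel ** 2


# Marker panels used throughout the analyses.  Genes absent from a dataset's
# probe panel are dropped with a logged warning, never silently.
DEFAULT_GENE_PANELS: dict[str, tuple[str, ...]] = {
    "isg": ("Ifit1", "Ifit2", "Irf7", "Ifnar1", "Usp18", "Isg15", "Cxcl10"),
    "exhaustion": (
        "Pdcd1", "Havcr2", "Lag3", "Tigit", "Ctla4",
        "Cd244", "Cd160", "Cd96", "Cd38", "Tox",
    ),
    "tcell": ("Cd3e", "Cd4", "Cd8b1", "Foxp3", "Trbc", "Trdc", "Cd163l1n", "Ccr7"),
    "microglia": (
        "Cst3", "Hexb", "Tyrobp", "Ctsd", "P2ry12", "Tmem119", "Tgfbr1",
        "Olfml3", "Cst7", "Apoe", "Lpl", "Trem2", "Srgap2", "Nav2",
    ),
}


@dataclasses.dataclass
class RunConfig:
    """Flat parameter document for a pipeline run.

    Parameters
    ----------
    zone_radius:
        Outer radius of the plaque-adjacent zone, µm.
    pixel_scale:
        Rendered-image pixel size.
    plaque_threshold_method:
        ``"otsu"`` (default, parameter-free) or ``"fixed"``.
    plaque_fixed_threshold:
        Threshold on the min-max normalized [0, 1] scale when method is fixed.
    plaque_min_area:
        Components smaller than this (µm²) are discarded as noise.
    histogram_bin_width:
        Distance-histogram bin width, µm.
    histogram_max_range:
        Distance-histogram range, µm; must be a multiple of the bin width.
    rng_seed:
        Seed for every stochastic step of a run.
    gene_panels:
        Named, non-empty marker gene lists.
    """

    zone_radius: float = DEFAULT_ZONE_RADIUS_UM
    pixel_scale: PixelScale = dataclasses.field(default_factory=PixelScale)
    plaque_threshold_method: str = "otsu"
    plaque_fixed_threshold: float | None = None
    plaque_min_area: float = 10.0
    histogram_bin_width: float = 5.0
    histogram_max_range: float = 200.0
    rng_seed: int = 0
    gene_panels: dict[str, tuple[str, ...]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GENE_PANELS)
    )

    def __post_init__(self) -> None:
        if not self.zone_radius > 0:
            raise ValueError("zone_radius must be > 0")
        if not self.histogram_bin_width > 0:
            raise ValueError("histogram_bin_width must be > 0")
        if self.plaque_threshold_method not in ("otsu", "fixed"):
            raise ValueError(
                f"unknown threshold method {self.plaque_threshold_method!r}"
            )
        for name, genes in self.gene_panels.items():
            if len(genes) == 0:
                raise ValueError(f"gene panel {name!r} is empty")
        if len(set(self.gene_panels)) != len(self.gene_panels):
            raise ValueError("gene panel names must be unique")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat YAML/JSON config; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pixel_scale" in raw:
            raw["pixel_scale"] = PixelScale(float(raw["pixel_scale"]))
        if "gene_panels" in raw:
            raw["gene_panels"] = {
                k: tuple(v) for k, v in raw["gene_panels"].items()
            }
        return cls(**raw)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["pixel_scale"] = self.pixel_scale.microns_per_pixel
        d["gene_panels"] = {k: list(v) for k, v in self.gene_panels.items()}
        return d

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_manifest(), indent=2))
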