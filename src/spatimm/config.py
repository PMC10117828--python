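"""Pipeline configuration.

Every constant of the published analysis protocol is a default here, never
hard-coded downstream: 0.2 µm/pixel scanning resolution, 1000-pixel tiles,
100 µm invasive-margin band, middle-slide registration reference, and the
25-percentile Immunoscore boundary.  Configs round-trip losslessly through
YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # geometry / scanning
    resolution: float = 0.2  # µm per pixel
    tile_side: int = 1000  # pixels
    im_width: float = 100.0  # µm
    im_side: str = "both"  # IM band sidedness: both | outer | inner
    disjoint_regions: bool = False  # exclude inner half-band from the TC density region
    mh_tile_side: int | None = None  # MH tiling; None = reuse the hotspot grid
    markers: tuple[str, ...] = ("CD3", "CD4", "CD8", "CK", "CD19", "CD163")  # section order
    # registration
    reference_index: int | None = None  # None = middle slide
    target_side: int = 500  # working raster pixels
    raster_sigma: float = 3.0
    nonrigid: bool = True
    # Immunoscore
    immunoscore_boundary: float = 25.0
    percentile_method: str = "rank"
    # statistics
    stage_subset_rule: str = "IIB+"
    welch: bool = False
    fdr: bool = False
    n_permutations: int = 0
    ki67_threshold: float = 14.0
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "spatimm_out"

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["markers"] = list(self.markers)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "markers" in data:
            data["markers"] = tuple(data["markers"])
        return cls(**data)

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)
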