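"""Analysis regions and tile grids.

The annotated geometry on each patient's reference slide consists of the
tumor-core polygon (TC) and the invasive front (IF), the TC boundary curve.
The invasive margin (IM) is the band of tissue within ``im_width`` micrometres
(default 100) of the IF.  Downstream quantification reports densities in TC,
IM and their union, and ranks cell densities over a square tile grid whose
tiles count as *effective* for a region when at least half of the tile area
lies inside that region.

Conventions fixed here (they remove every coordinate ambiguity):

* all coordinates are in micrometres;
* the IM band is symmetric about the IF by default (``side="both"``);
  one-sided variants are available because sidedness is a modelling choice;
* TC and IM may overlap near the front; ``disjoint=True`` removes the inner
  half-band from TC;
* region membership is closed on the boundary (a point exactly on the IF
  belongs to both TC and IM);
* tiles are half-open axis-aligned squares, 0-based ``(ix, iy)`` indices,
  origin at the slide-extent minimum; edge tiles may extend past the extent
  but keep their nominal area;
* a tile with intersection area exactly half the tile area is effective
  (``>=`` rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon, box
from shapely.prepared import prep
from shapely.geometry.base import BaseGeometry

__all__ = [
    "RegionAnnotation",
    "TileGrid",
    "build_im_band",
    "assign_region",
    "make_tile_grid",
    "effective_tiles",
]


@dataclass(frozen=True)
class RegionAnnotation:
    """Tumor-core polygon plus invasive-front polyline, in micrometres."""

    tc_polygon: Polygon
    if_polyline: LineString
    im_width: float = 100.0

    def __post_init__(self) -> None:
        if self.im_width <= 0:
            raise ValueError(f"im_width must be > 0, got {self.im_width}")
        if self.if_polyline.length == 0:
            raise ValueError("invasive-front polyline is degenerate (zero length)")
        if not self.tc_polygon.is_valid or self.tc_polygon.area == 0:
            raise ValueError("tumor-core polygon is degenerate or invalid")

    @classmethod
    def from_polygon(cls, tc_polygon: Polygon, im_width: float = 100.0) -> "RegionAnnotation":
        """Annotation whose IF is exactly the TC boundary."""
        return cls(tc_polygon=tc_polygon, if_polyline=LineString(tc_polygon.exterior.coords), im_width=im_width)


def build_im_band(
    annotation: RegionAnnotation,
    extent: tuple[float, float, float, float] | None = None,
    side: str = "both",
) -> BaseGeometry:
    """Invasive-margin band: all points within ``im_width`` of the IF.

    Parameters
    ----------
    annotation:
        TC/IF annotation.
    extent:
        Optional ``(xmin, ymin, xmax, ymax)`` slide extent the band is
        clipped to.
    side:
        ``"both"`` (default), ``"outer"`` (band minus TC interior) or
        ``"inner"`` (band intersected with TC).
    """
    band = annotation.if_polyline.buffer(annotation.im_width)
    if side == "outer":
        band = band.difference(annotation.tc_polygon)
    elif side == "inner":
        band = band.intersection(annotation.tc_polygon)
    elif side != "both":
        raise ValueError(f"side must be 'both', 'outer' or 'inner', got {side!r}")
    if extent is not None:
        band = band.intersection(box(*extent))
    if band.is_empty:
        raise ValueError("IM band is empty (degenerate annotation or extent)")
    return band


def assign_region(
    points: np.ndarray,
    annotation: RegionAnnotation,
    im_band: BaseGeometry | None = None,
) -> dict[str, np.ndarray]:
    """Label each point as TC / IM / TC+IM / outside.

    Membership is closed on boundaries: a point on the IF is in both TC and
    IM.  Returns boolean masks ``in_tc`` and ``in_im`` plus a string
    ``label`` array; ``"TC+IM"`` means the point is in both regions.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if im_band is None:
        im_band = build_im_band(annotation)
    x, y = pts[:, 0], pts[:, 1]
    # intersects_xy includes the boundary, i.e. the closed-region convention
    in_tc = shapely.intersects_xy(annotation.tc_polygon, x, y)
    in_im = shapely.intersects_xy(im_band, x, y)
    label = np.full(len(pts), "outside", dtype=object)
    label[in_tc & ~in_im] = "TC"
    label[~in_tc & in_im] = "IM"
    label[in_tc & in_im] = "TC+IM"
    return {"in_tc": in_tc, "in_im": in_im, "label": label}


@dataclass
class TileGrid:
    """Half-open square tile grid over a slide extent.

    ``tile_side`` is in pixels; the physical tile side is
    ``tile_side * resolution`` micrometres (1000 px at 0.2 µm/px = 200 µm).
    """

    origin: tuple[float, float]
    nx: int
    ny: int
    tile_side: int = 1000
    resolution: float = 0.2
    effective: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tile_side < 1:
            raise ValueError("tile_side must be >= 1 pixel")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must contain at least one tile")

    @property
    def side_um(self) -> float:
        return self.tile_side * self.resolution

    @property
    def tile_area_mm2(self) -> float:
        return (self.side_um / 1000.0) ** 2

    @property
    def n_tiles(self) -> int:
        return self.nx * self.ny

    def tile_polygon(self, ix: int, iy: int) -> Polygon:
        x0 = self.origin[0] + ix * self.side_um
        y0 = self.origin[1] + iy * self.side_um
        return box(x0, y0, x0 + self.side_um, y0 + self.side_um)

    def tile_index(self, points: np.ndarray) -> np.ndarray:
        """Flat tile index (iy * nx + ix) per point; -1 if off-grid."""
        pts = np.asarray(points, dtype=float)
        ix = np.floor((pts[:, 0] - self.origin[0]) / self.side_um).astype(int)
        iy = np.floor((pts[:, 1] - self.origin[1]) / self.side_um).astype(int)
        ok = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        flat = np.where(ok, iy * self.nx + ix, -1)
        return flat

    def counts(self, points: np.ndarray) -> np.ndarray:
        """Point counts per tile, flat array of length nx * ny."""
        flat = self.tile_index(points)
        flat = flat[flat >= 0]
        return np.bincount(flat, minlength=self.n_tiles)


def make_tile_grid(
    extent: tuple[float, float, float, float],
    resolution: float = 0.2,
    tile_side: int = 1000,
) -> TileGrid:
    """Build the tile grid covering ``extent`` (µm), origin at its minimum."""
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"non-positive extent {extent}")
    side_um = tile_side * resolution
    nx = int(np.ceil((xmax - xmin) / side_um))
    ny = int(np.ceil((ymax - ymin) / side_um))
    return TileGrid(origin=(xmin, ymin), nx=nx, ny=ny, tile_side=tile_side, resolution=resolution)


def effective_tiles(
    grid: TileGrid,
    region: BaseGeometry,
    name: str = "region",
    threshold: float = 0.5,
) -> np.ndarray:
    """Flag tiles with >= ``threshold`` of their area inside ``region``.

    Exact polygon clipping per tile; the flag array (flat, length nx*ny) is
    also cached on ``grid.effective[name]``.
    """
    if region.is_empty:
        raise ValueError("region is empty")
    flags = np.zeros(grid.n_tiles, dtype=bool)
    need = threshold * grid.side_um**2
    rxmin, rymin, rxmax, rymax = region.bounds
    prepared = prep(region)
    for iy in range(grid.ny):
        y0 = grid.origin[1] + iy * grid.side_um
        if y0 > rymax or y0 + grid.side_um < rymin:
            continue
        for ix in range(grid.nx):
            x0 = grid.origin[0] + ix * grid.side_um
            if x0 > rxmax or x0 + grid.side_um < rxmin:
                continue
            tile = box(x0, y0, x0 + grid.side_um, y0 + grid.side_um)
            if prepared.contains(tile):
                flags[iy * grid.nx + ix] = True
            elif prepared.intersects(tile):
                flags[iy * grid.nx + ix] = region.intersection(tile).area >= need
    grid.effective[name] = flags
    return flags
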