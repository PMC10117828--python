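"""Per-patient spatial parameters.

Three families of parameters are computed per patient from the registered
point patterns and the region annotation:

* **region densities** — positive cells per mm² in the tumor core (TC), the
  invasive margin (IM) and their union (TC+IM), for each immune marker;
* **hotspots** — the slide is cut into 1000 × 1000-pixel tiles (200 µm at
  0.2 µm/pixel); tiles with at least half their area in the TC count as
  effective; the three highest per-tile densities are Hotspot1–3;
* **Morisita–Horn colocalization** — for two markers with tile proportions
  ``p_i`` and ``q_i`` over the same R tiles,

      MH = 2 Σ_i p_i q_i / (Σ_i p_i² + Σ_i q_i²),

  a symmetric overlap index in [0, 1] (1 = identical spatial distribution).
  The MH tiling reuses the hotspot grid over tiles effective for TC ∪ IM.

With the default six markers the per-patient vector has 47 entries:
15 region densities, 15 hotspot densities, 10 pairwise immune MH indices,
5 CK–marker MH indices, the CK–pooled-immune MH index, and the Immunoscore
(appended at cohort level, since it needs cohort percentiles).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .regions import RegionAnnotation, TileGrid, build_im_band, effective_tiles, make_tile_grid
from .registration import MarkerPointPattern

__all__ = [
    "TileDistribution",
    "MHResult",
    "HotspotResult",
    "region_density",
    "tile_densities",
    "hotspot_top3",
    "tile_distribution",
    "mh_index",
    "mh_pooled_immune_vs_ck",
    "parameter_columns",
    "parameter_vector",
]

IMMUNE_MARKERS = ("CD3", "CD4", "CD8", "CD19", "CD163")
TUMOR_MARKER = "CK"
# CK rows follow the published table ordering (CD8 listed last)
CK_PAIR_ORDER = ("CD3", "CD4", "CD19", "CD163", "CD8")


def region_density(pattern: MarkerPointPattern, region) -> float:
    """Positive-cell density in cells/mm²: point count in region / area."""
    import shapely

    area_mm2 = region.area / 1e6
    if area_mm2 <= 0:
        raise ValueError("region area must be > 0")
    if pattern.n == 0:
        return 0.0
    inside = shapely.intersects_xy(region, pattern.points[:, 0], pattern.points[:, 1])
    return float(inside.sum() / area_mm2)


def tile_densities(
    pattern: MarkerPointPattern, grid: TileGrid, effective: np.ndarray
) -> np.ndarray:
    """Density (cells/mm²) for every effective tile; NaN elsewhere.

    The denominator is the nominal tile area (edge tiles are not
    area-corrected), so tile densities are directly comparable.
    """
    if not effective.any():
        warnings.warn("no effective tiles", stacklevel=2)
        return np.full(grid.n_tiles, np.nan)
    counts = grid.counts(pattern.points)
    dens = np.full(grid.n_tiles, np.nan)
    dens[effective] = counts[effective] / grid.tile_area_mm2
    return dens


@dataclass(frozen=True)
class HotspotResult:
    marker: str
    densities: tuple[float, float, float]  # descending; NaN-padded if < 3 tiles
    tile_indices: tuple[int, int, int]  # flat indices; -1 where padded


def hotspot_top3(densities: np.ndarray, marker: str = "") -> HotspotResult:
    """Top-3 tile densities, ties broken by ascending flat tile index."""
    d = np.asarray(densities, dtype=float)
    valid = np.flatnonzero(np.isfinite(d))
    if len(valid) == 0:
        raise ValueError("no effective tiles to rank")
    order = valid[np.lexsort((valid, -d[valid]))]
    top = order[:3]
    dens = [float(d[i]) for i in top] + [np.nan] * (3 - len(top))
    idx = [int(i) for i in top] + [-1] * (3 - len(top))
    return HotspotResult(marker, tuple(dens), tuple(idx))


@dataclass(frozen=True)
class TileDistribution:
    """Per-tile proportions of one marker over the R included tiles."""

    marker: str
    proportions: np.ndarray
    R: int

    @classmethod
    def from_counts(cls, counts: np.ndarray, marker: str = "") -> "TileDistribution":
        c = np.asarray(counts, dtype=float)
        total = c.sum()
        p = c / total if total > 0 else np.zeros_like(c)
        return cls(marker, p, len(c))


def tile_distribution(
    pattern: MarkerPointPattern, grid: TileGrid, effective: np.ndarray
) -> TileDistribution:
    counts = grid.counts(pattern.points)[effective]
    return TileDistribution.from_counts(counts, pattern.marker)


@dataclass(frozen=True)
class MHResult:
    pair: tuple[str, str]
    value: float
    R: int


def mh_index(a: TileDistribution, b: TileDistribution) -> MHResult:
    """Morisita–Horn index of two tile distributions on the same grid."""
    if a.R != b.R:
        raise ValueError(f"tile counts differ ({a.R} vs {b.R}); same grid required")
    pa, pb = a.proportions, b.proportions
    denom = float((pa**2).sum() + (pb**2).sum())
    if (pa.sum() == 0) or (pb.sum() == 0):
        warnings.warn(f"MH undefined for empty distribution in pair ({a.marker}, {b.marker})",
                      stacklevel=2)
        return MHResult((a.marker, b.marker), np.nan, a.R)
    value = 2.0 * float((pa * pb).sum()) / denom
    return MHResult((a.marker, b.marker), value, a.R)


def mh_pooled_immune_vs_ck(
    immune_patterns: list[MarkerPointPattern],
    ck_pattern: MarkerPointPattern,
    grid: TileGrid,
    effective: np.ndarray,
) -> MHResult:
    """Pool all immune-marker points into one distribution, then MH vs CK."""
    nonempty = [p for p in immune_patterns if p.n > 0]
    if not nonempty:
        warnings.warn("all immune patterns empty; pooled MH undefined", stacklevel=2)
        return MHResult(("Immune", ck_pattern.marker), np.nan, int(effective.sum()))
    pooled_pts = np.vstack([p.points for p in nonempty])
    pooled = MarkerPointPattern("Immune", pooled_pts, ck_pattern.slide_extent, ck_pattern.resolution)
    return mh_index(
        tile_distribution(pooled, grid, effective),
        tile_distribution(ck_pattern, grid, effective),
    )


def parameter_columns(
    markers: tuple[str, ...] = IMMUNE_MARKERS, include_pooled: bool = True
) -> list[str]:
    """The 47 parameter names in the published table's reading order.

    ``include_pooled=False`` drops the CK-pooled-immune column, giving the
    46-row variant of the layout.
    """
    cols = [f"{region}-{m}" for region in ("TC", "IM", "TC+IM") for m in markers]
    cols += [f"Hotspot{k}-{m}" for k in (1, 2, 3) for m in markers]
    cols += [f"{a}-{b}" for a, b in itertools.combinations(markers, 2)]
    cols += [f"{TUMOR_MARKER}-{m}" for m in CK_PAIR_ORDER if m in markers]
    if include_pooled:
        cols.append(f"{TUMOR_MARKER}-Immune")
    cols.append("Immunoscore")
    return cols


def parameter_vector(
    slides: dict[str, MarkerPointPattern],
    annotation: RegionAnnotation,
    slide_extent: tuple[float, float, float, float],
    resolution: float = 0.2,
    tile_side: int = 1000,
    im_side: str = "both",
    disjoint_regions: bool = False,
    mh_tile_side: int | None = None,
) -> dict[str, float]:
    """Assemble one patient's spatial parameter vector.

    ``slides`` maps marker name to its registered (reference-frame) point
    pattern.  A missing or empty marker slide leaves all entries that
    depend on it as NaN; the Immunoscore slot is NaN here and filled at
    cohort level.  ``disjoint_regions`` excludes the inner half of the IM
    band from the TC density region; ``mh_tile_side`` lets the MH tiling
    differ from the hotspot tiling (default: same grid).  Returns a dict
    in :func:`parameter_columns` order.
    """
    tc = annotation.tc_polygon
    band = build_im_band(annotation, extent=slide_extent, side=im_side)
    union = tc.union(band)
    tc_density_region = tc.difference(band) if disjoint_regions else tc
    grid = make_tile_grid(slide_extent, resolution=resolution, tile_side=tile_side)
    eff_tc = effective_tiles(grid, tc, "TC")
    mh_grid = (
        grid
        if mh_tile_side is None or mh_tile_side == tile_side
        else make_tile_grid(slide_extent, resolution=resolution, tile_side=mh_tile_side)
    )
    eff_union = effective_tiles(mh_grid, union, "TC+IM")

    def present(m: str) -> bool:
        return m in slides and slides[m].n > 0

    out: dict[str, float] = {c: np.nan for c in parameter_columns()}
    for m in IMMUNE_MARKERS:
        if not present(m):
            continue
        pat = slides[m]
        out[f"TC-{m}"] = region_density(pat, tc_density_region)
        out[f"IM-{m}"] = region_density(pat, band)
        out[f"TC+IM-{m}"] = region_density(pat, union)
        if eff_tc.any():
            hs = hotspot_top3(tile_densities(pat, grid, eff_tc), m)
            for k in range(3):
                out[f"Hotspot{k + 1}-{m}"] = hs.densities[k]
    dists = {
        m: tile_distribution(slides[m], mh_grid, eff_union)
        for m in (*IMMUNE_MARKERS, TUMOR_MARKER)
        if present(m)
    }
    for a, b in itertools.combinations(IMMUNE_MARKERS, 2):
        if a in dists and b in dists:
            out[f"{a}-{b}"] = mh_index(dists[a], dists[b]).value
    if TUMOR_MARKER in dists:
        for m in CK_PAIR_ORDER:
            if m in dists:
                out[f"{TUMOR_MARKER}-{m}"] = mh_index(dists[TUMOR_MARKER], dists[m]).value
        immune_present = [slides[m] for m in IMMUNE_MARKERS if present(m)]
        if immune_present:
            out[f"{TUMOR_MARKER}-Immune"] = mh_pooled_immune_vs_ck(
                immune_present, slides[TUMOR_MARKER], mh_grid, eff_union
            ).value
    return out
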