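"""Reading and writing the pipeline's file formats.

* **cell tables** — CSV with columns ``slide_id, marker, x_um, y_um,
  positive``, one row per detected cell, coordinates in µm (the shape of a
  QuPath detection export after unit conversion);
* **annotations** — GeoJSON FeatureCollection with a Polygon feature
  (``properties.region == "TC"``) and a LineString feature
  (``properties.region == "IF"``), coordinates in µm;
* **clinical tables** — CSV with one row per patient (survival months,
  event flags, group flags, covariates);
* **outputs** — TSV tables plus a JSON run manifest.

The synthetic-cohort writer emits exactly these formats, so synthetic
cohorts are indistinguishable from real input on disk.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon, mapping, shape

from .regions import RegionAnnotation
from .registration import MarkerPointPattern
from .stats import SurvivalRecord

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_annotation",
    "write_annotation",
    "read_clinical",
    "write_clinical",
    "write_cohort",
]

CELL_COLUMNS = ["slide_id", "marker", "x_um", "y_um", "positive"]


def read_cell_table(
    path: str | Path,
    slide_extent: tuple[float, float, float, float],
    resolution: float = 0.2,
) -> tuple[dict[str, MarkerPointPattern], int]:
    """Load per-marker point patterns from a cell-table CSV.

    All detected cells are loaded; the ``positive`` column becomes the
    pattern's positivity mask.  Returns ``(patterns, n_rejected)``; rows
    with non-numeric coordinates are rejected and counted, missing
    required columns raise immediately.
    """
    df = pd.read_csv(path, dtype={"slide_id": str, "marker": str})
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table {path} is missing required column(s): {missing}")
    x = pd.to_numeric(df["x_um"], errors="coerce")
    y = pd.to_numeric(df["y_um"], errors="coerce")
    bad = x.isna() | y.isna()
    n_rejected = int(bad.sum())
    if n_rejected:
        warnings.warn(f"{path}: rejected {n_rejected} malformed row(s)", stacklevel=2)
    df = df.loc[~bad].assign(x_um=x[~bad], y_um=y[~bad])
    patterns: dict[str, MarkerPointPattern] = {}
    for marker, sub in df.groupby("marker", sort=False):
        patterns[str(marker)] = MarkerPointPattern(
            str(marker),
            sub[["x_um", "y_um"]].to_numpy(float),
            slide_extent,
            resolution,
            positive=pd.to_numeric(sub["positive"], errors="coerce").fillna(0).to_numpy() > 0,
        )
    if not patterns:
        warnings.warn(f"{path}: no cells loaded", stacklevel=2)
    return patterns, n_rejected


def write_cell_table(patterns: dict[str, MarkerPointPattern], path: str | Path) -> None:
    frames = []
    for marker, pat in patterns.items():
        frames.append(
            pd.DataFrame(
                {
                    "slide_id": marker,
                    "marker": marker,
                    "x_um": np.round(pat.points[:, 0], 3),
                    "y_um": np.round(pat.points[:, 1], 3),
                    "positive": pat.positive.astype(int),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=CELL_COLUMNS)
    df.to_csv(path, index=False)


def read_annotation(path: str | Path, im_width: float = 100.0) -> RegionAnnotation:
    """TC polygon + IF polyline from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        gj = json.load(fh)
    tc = None
    ifl = None
    for feat in gj.get("features", []):
        region = feat.get("properties", {}).get("region")
        geom = shape(feat["geometry"])
        if region == "TC":
            tc = geom
        elif region == "IF":
            ifl = geom
    if tc is None:
        raise ValueError(f"{path}: no feature with properties.region == 'TC'")
    if ifl is None:
        ifl = LineString(tc.exterior.coords)
    return RegionAnnotation(tc_polygon=tc, if_polyline=ifl, im_width=im_width)


def write_annotation(tc_polygon: Polygon, path: str | Path, if_polyline: LineString | None = None) -> None:
    if if_polyline is None:
        if_polyline = LineString(tc_polygon.exterior.coords)
    gj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"region": "TC"}, "geometry": mapping(tc_polygon)},
            {"type": "Feature", "properties": {"region": "IF"}, "geometry": mapping(if_polyline)},
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


CLINICAL_COLUMNS = [
    "patient_id", "dfs_months", "dfs_event", "os_months", "os_event",
    "recurrence", "metastasis", "stage", "age_group", "tumor_size_cm",
    "grade", "ki67_pct", "p53_positive", "basal_like",
]


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "stage": str, "age_group": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} is missing column(s): {missing}")
    for c in ("dfs_event", "os_event", "recurrence", "metastasis"):
        df[c] = df[c].astype(bool)
    return df.set_index("patient_id")


def write_clinical(records: list[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records])[CLINICAL_COLUMNS].to_csv(path, index=False)


def _transform_polygon(poly: Polygon, transform, max_segment: float = 25.0) -> Polygon:
    dense = poly.segmentize(max_segment)
    coords = np.asarray(dense.exterior.coords)
    return Polygon(transform.apply(coords))


def write_cohort(cohort, outdir: str | Path) -> Path:
    """Write a synthetic cohort in the pipeline's input layout.

    ``outdir/clinical.csv`` plus one directory per patient holding
    ``cells.csv`` (observed, misaligned coordinates) and
    ``annotation.geojson``.  The annotation is expressed in the reference
    (middle) slide's frame — the frame a pathologist would annotate on —
    by pushing the true geometry through that slide's planted misalignment.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    markers = list(cohort.spec.markers)
    ref_marker = markers[len(markers) // 2]
    for patient in cohort.patients:
        pdir = outdir / patient.patient_id
        pdir.mkdir(exist_ok=True)
        write_cell_table(patient.slides, pdir / "cells.csv")
        tc_ref = _transform_polygon(patient.geometry.tc_polygon, patient.transforms[ref_marker])
        write_annotation(tc_ref, pdir / "annotation.geojson")
    write_clinical([p.clinical for p in cohort.patients], outdir / "clinical.csv")
    meta = {
        "n_patients": cohort.spec.n_patients,
        "markers": markers,
        "reference_marker": ref_marker,
        "slide_extent": list(cohort.spec.slide_extent),
        "resolution": cohort.spec.resolution,
        "seed": cohort.spec.seed,
    }
    with open(outdir / "cohort.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return outdir
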