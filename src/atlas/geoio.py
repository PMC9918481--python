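"""File I/O and district zonal summaries.

Rasters are float32 GeoTIFFs with nodata −9999 and the standard GeoTIFF
placement tags (ModelPixelScale, ModelTiepoint) carrying the planar-km
geotransform; values are float64 with NaN in memory, rounded to float32
at write time. Districts travel as GeoJSON FeatureCollections; clusters
as CSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .domain import StudyDomain
from .grids import NODATA, CovariateGrid, GridTransform

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

CLUSTER_COLUMNS = ["cluster_id", "x", "y", "urban", "m", "y_events"]


# --------------------------------------------------------------------------
# rasters
# --------------------------------------------------------------------------

def write_raster(grid: CovariateGrid, path) -> None:
    """Write a grid as a float32 GeoTIFF (nodata −9999, planar-km tags)."""
    t = grid.transform
    vals = np.where(np.isnan(grid.values), grid.nodata, grid.values).astype(np.float32)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(t.cell), float(t.cell), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(t.x0), float(t.y1), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_raster(path) -> CovariateGrid:
    """Read a GeoTIFF written by :func:`write_raster` (or compatible)."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        vals = page.asarray().astype(float)
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(
                f"{path}: missing GeoTIFF placement tags (ModelPixelScale/ModelTiepoint); "
                "write rasters with atlas.geoio.write_raster or supply a georeferenced TIFF")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        nodata = float(tags[_TAG_GDAL_NODATA].value) if _TAG_GDAL_NODATA in tags else NODATA
    if abs(scale[0] - scale[1]) > 1e-12:
        raise ValueError(f"{path}: non-square cells not supported ({scale[0]} × {scale[1]})")
    # tiepoint maps raster (i,j,k) -> model (x,y,z); we write the upper-left corner
    x0 = tie[3] - tie[0] * scale[0]
    y1 = tie[4] + tie[1] * scale[1]
    vals[vals == nodata] = np.nan
    name = Path(path).stem
    return CovariateGrid(values=vals, transform=GridTransform(x0=x0, y1=y1, cell=scale[0]),
                         name=name, nodata=nodata)


def read_raster_stack(paths) -> list[CovariateGrid]:
    """Read several rasters that must share shape and transform."""
    grids = [read_raster(p) for p in paths]
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape or g.transform != ref.transform:
            raise ValueError(f"raster {g.name!r} does not match {ref.name!r} in "
                             "shape/transform")
    return grids


# --------------------------------------------------------------------------
# districts (GeoJSON)
# --------------------------------------------------------------------------

def write_districts(domain: StudyDomain, path) -> None:
    """Write district polygons as a GeoJSON FeatureCollection."""
    features = []
    for did, poly in domain.districts:
        features.append({
            "type": "Feature",
            "properties": {"district_id": int(did)},
            "geometry": mapping(poly),
        })
    fc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"extent": list(domain.extent), "crs_note": domain.crs_note},
    }
    with open(path, "w") as fh:
        json.dump(fc, fh, sort_keys=True)


def read_districts(path) -> StudyDomain:
    """Read a GeoJSON FeatureCollection of district polygons."""
    with open(path) as fh:
        fc = json.load(fh)
    districts = []
    for i, feat in enumerate(fc.get("features", [])):
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"feature {i} (district_id="
                             f"{feat.get('properties', {}).get('district_id')}) has an "
                             "invalid ring")
        districts.append((int(feat["properties"]["district_id"]), geom))
    props = fc.get("properties", {})
    if "extent" in props:
        extent = tuple(props["extent"])
    else:
        from shapely.ops import unary_union
        extent = tuple(float(b) for b in unary_union([g for _, g in districts]).bounds)
    return StudyDomain(extent=extent, districts=districts,
                       crs_note=props.get("crs_note", "planar-km (local projection)"))


# --------------------------------------------------------------------------
# clusters (CSV)
# --------------------------------------------------------------------------

def write_clusters(clusters: pd.DataFrame, path) -> None:
    """Write the cluster table to CSV (reported coordinates first)."""
    cov_cols = [c for c in clusters.columns if c.startswith("cov_")]
    extra = [c for c in ("x_true", "y_true", "far_rural", "p_true") if c in clusters.columns]
    cols = CLUSTER_COLUMNS + extra + cov_cols
    clusters.to_csv(path, index=False, columns=[c for c in cols if c in clusters.columns],
                    float_format="%.10g")


def read_clusters(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing cluster columns {missing}")
    return df


# --------------------------------------------------------------------------
# zonal summaries
# --------------------------------------------------------------------------

@dataclass
class ZonalSummary:
    """Zonal mean of a surface over one district."""

    district_id: int
    mean: float
    n_cells: int


def zonal_mean(grid: CovariateGrid, districts: list[tuple[int, BaseGeometry]],
               ) -> list[ZonalSummary]:
    """Unweighted mean of unmasked cell values per district.

    A cell belongs to the district containing its center; centers that
    fall exactly on a shared boundary are resolved by nudging the test
    point by +1e-9 cells in x and y (the half-open rule), so no cell is
    counted twice when districts tile the domain. Districts with no
    contributing cells get a NaN mean and a warning.
    """
    xs, ys = grid.transform.cell_centers(grid.shape)
    cx, cy = np.meshgrid(xs, ys)
    delta = 1e-9 * grid.transform.cell
    px = (cx + delta).ravel()
    py = (cy + delta).ravel()
    vals = grid.values.ravel()
    unmasked = ~np.isnan(vals)
    out = []
    for did, poly in districts:
        inside = shapely.contains_xy(poly, px, py)
        use = inside & unmasked
        n = int(use.sum())
        if n == 0:
            warnings.warn(f"district {did}: no contributing cells", RuntimeWarning,
                          stacklevel=2)
            out.append(ZonalSummary(district_id=did, mean=float("nan"), n_cells=0))
        else:
            out.append(ZonalSummary(district_id=did, mean=float(vals[use].mean()),
                                    n_cells=n))
    return out


def zonal_table(summaries: list[ZonalSummary]) -> pd.DataFrame:
    return pd.DataFrame([{"district_id": s.district_id, "mean": s.mean,
                          "n_cells": s.n_cells} for s in summaries])
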