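"""Raster and vector I/O.

Rasters are single-band float64 GeoTIFFs in geographic lon/lat (WGS84),
written and read through :mod:`tifffile` with the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the GDAL nodata tag.
Masked cells are stored as the grid's nodata value and restored to the mask
on read, so a write/read round trip is bit exact.

Vectors are GeoJSON FeatureCollections; zone features carry ``zone_id`` and
``region_id`` properties.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import shape as _geojson_shape

from .grid import GridSpec, RasterLayer, Zone, ZoneSet

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# Minimal GeoTIFF key directory: geographic model, WGS84 (EPSG:4326),
# area-based raster space.
_GEO_KEYS = (
    1, 1, 0, 3,
    1024, 0, 1, 2,      # GTModelTypeGeoKey = geographic
    1025, 0, 1, 1,      # GTRasterTypeGeoKey = PixelIsArea
    2048, 0, 1, 4326,   # GeographicTypeGeoKey = WGS84
)


def write_geotiff(path: str | Path, layer: RasterLayer) -> None:
    """Write a layer as a single-band float64 GeoTIFF."""
    grid = layer.grid
    data = layer.filled()
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_GEO_KEYS), _GEO_KEYS),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)),
    ]
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        extratags=extratags,
        metadata=None,
        description=json.dumps({"units": layer.units}),
    )


def read_geotiff(path: str | Path) -> RasterLayer:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(np.float64)
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
        units = ""
        desc = page.description
        if desc:
            try:
                units = json.loads(desc).get("units", "")
            except (json.JSONDecodeError, AttributeError):
                units = ""
    if scale[0] != scale[1]:
        raise ValueError("anisotropic pixels are not supported")
    # tiepoint maps raster (0,0) corner to (origin_lon, origin_lat)
    grid = GridSpec(
        origin_lon=float(tiepoint[3]) - float(tiepoint[0]) * float(scale[0]),
        origin_lat=float(tiepoint[4]) + float(tiepoint[1]) * float(scale[1]),
        cell_size=float(scale[0]),
        n_rows=data.shape[0],
        n_cols=data.shape[1],
        nodata=nodata,
    )
    mask = ~(np.isclose(data, nodata, rtol=0, atol=0) | np.isnan(data))
    values = data.copy()
    values[~mask] = 0.0
    return RasterLayer(grid, values, units, mask)


# ---------------------------------------------------------------------------
# GeoJSON zones and polygons
# ---------------------------------------------------------------------------


def write_zones_geojson(path: str | Path, zones: ZoneSet) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"zone_id": z.zone_id, "region_id": z.region_id},
            "geometry": json.loads(shapely.to_geojson(z.geometry)),
        }
        for z in zones
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_zones_geojson(path: str | Path) -> ZoneSet:
    fc = json.loads(Path(path).read_text())
    zones = [
        Zone(
            zone_id=str(f["properties"]["zone_id"]),
            region_id=str(f["properties"].get("region_id", "")),
            geometry=_geojson_shape(f["geometry"]),
        )
        for f in fc["features"]
    ]
    return ZoneSet(zones)


__all__ = [
    "write_geotiff",
    "read_geotiff",
    "write_zones_geojson",
    "read_zones_geojson",
]
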