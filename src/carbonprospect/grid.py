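"""Grid model and raster primitives.

Everything downstream operates on :class:`RasterLayer` objects: 2-D double
precision fields on a regular geographic (lon/lat, WGS84) grid with an
explicit validity mask. Conventions, fixed package-wide:

* north-up row order — row 0 is the northernmost row;
* cell-center registration — the center of cell ``(i, j)`` is at
  ``(origin_lon + (j + 0.5) * cell_size, origin_lat - (i + 0.5) * cell_size)``
  where ``origin`` is the north-west corner of the grid;
* strict mask propagation — any arithmetic involving a masked cell yields a
  masked cell;
* spherical Earth of radius 6,371,000 m for cell areas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

EARTH_RADIUS_M = 6_371_000.0
#: Tropic of Cancer / Capricorn latitude used for the pantropical band.
TROPIC_LAT = 23.44
#: Nominal analysis resolution in degrees (~1 km at the equator).
DEFAULT_CELL_SIZE = 0.00833


class GridMismatchError(ValueError):
    """Raised when two grids are not compatible for cell-wise arithmetic."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid.

    ``origin_lon`` / ``origin_lat`` locate the north-west *corner* of the
    grid. Two grids are compatible for arithmetic only if all fields match
    exactly.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        j = np.arange(self.n_cols, dtype=np.float64)
        return self.origin_lon + (j + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        i = np.arange(self.n_rows, dtype=np.float64)
        return self.origin_lat - (i + 0.5) * self.cell_size

    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer edges."""
        return (
            self.origin_lon,
            self.origin_lat - self.n_rows * self.cell_size,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat,
        )

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            self.origin_lon == other.origin_lon
            and self.origin_lat == other.origin_lat
            and self.cell_size == other.cell_size
            and self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
        )


def _check_compatible(a: GridSpec, b: GridSpec) -> None:
    if not a.same_geometry(b):
        raise GridMismatchError("grid mismatch: layers are on different grids")


@dataclass
class RasterLayer:
    """A 2-D field with units and per-cell validity.

    ``mask`` is True on valid cells. Arithmetic propagates invalidity
    strictly: a masked operand masks the result.
    """

    grid: GridSpec
    values: np.ndarray
    units: str = ""
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape does not match grid shape")

    # -- constructors -------------------------------------------------
    @classmethod
    def full(cls, grid: GridSpec, value: float, units: str = "") -> "RasterLayer":
        return cls(grid, np.full(grid.shape, value, dtype=np.float64), units)

    def copy(self) -> "RasterLayer":
        return RasterLayer(self.grid, self.values.copy(), self.units, self.mask.copy())

    def with_values(self, values: np.ndarray, units: str | None = None) -> "RasterLayer":
        return RasterLayer(
            self.grid,
            np.asarray(values, dtype=np.float64),
            self.units if units is None else units,
            self.mask.copy(),
        )

    # -- arithmetic with strict mask propagation ----------------------
    def _binary(self, other, op, units: str | None = None) -> "RasterLayer":
        if isinstance(other, RasterLayer):
            _check_compatible(self.grid, other.grid)
            vals = op(self.values, other.values)
            mask = self.mask & other.mask
        else:
            vals = op(self.values, other)
            mask = self.mask.copy()
        return RasterLayer(self.grid, vals, units or self.units, mask)

    def __add__(self, other):
        return self._binary(other, np.add)

    def __sub__(self, other):
        return self._binary(other, np.subtract)

    def __mul__(self, other):
        return self._binary(other, np.multiply)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, np.divide)

    # -- summaries ----------------------------------------------------
    def sum(self) -> float:
        """Sum over unmasked cells."""
        return float(self.values[self.mask].sum())

    def filled(self, fill: float | None = None) -> np.ndarray:
        out = self.values.copy()
        out[~self.mask] = self.grid.nodata if fill is None else fill
        return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def resample_bilinear(layer: RasterLayer, target: GridSpec) -> RasterLayer:
    """Resample ``layer`` onto ``target`` by bilinear interpolation.

    Values at target cell centers are bilinear interpolations of the four
    surrounding source cell centers. Target cells whose 4-point support falls
    outside the source center lattice, or touches any masked source cell, are
    masked. Intended for coarsening or same-scale registration
    (``source.cell_size <= target.cell_size``).
    """
    src = layer.grid
    if src.cell_size > target.cell_size * (1 + 1e-12):
        raise ValueError("bilinear resampling expects source cell_size <= target")
    w1, s1, e1, n1 = src.bounds()
    w2, s2, e2, n2 = target.bounds()
    if e1 <= w2 or e2 <= w1 or n1 <= s2 or n2 <= s1:
        raise GridMismatchError("grid mismatch: source and target do not overlap")

    if src.same_geometry(target):
        return layer.copy()

    lon_t = target.lon_centers()
    lat_t = target.lat_centers()
    # fractional indices of target centers on the source center lattice
    fc = (lon_t - src.origin_lon) / src.cell_size - 0.5
    fr = (src.origin_lat - lat_t) / src.cell_size - 0.5
    fc2, fr2 = np.meshgrid(fc, fr)

    c0 = np.floor(fc2).astype(np.int64)
    r0 = np.floor(fr2).astype(np.int64)
    inside = (c0 >= 0) & (c0 + 1 <= src.n_cols - 1) & (r0 >= 0) & (r0 + 1 <= src.n_rows - 1)
    c0c = np.clip(c0, 0, src.n_cols - 2)
    r0c = np.clip(r0, 0, src.n_rows - 2)
    wx = fc2 - c0c
    wy = fr2 - r0c

    v = layer.values
    m = layer.mask
    v00 = v[r0c, c0c]
    v01 = v[r0c, c0c + 1]
    v10 = v[r0c + 1, c0c]
    v11 = v[r0c + 1, c0c + 1]
    out = (
        v00 * (1 - wx) * (1 - wy)
        + v01 * wx * (1 - wy)
        + v10 * (1 - wx) * wy
        + v11 * wx * wy
    )
    support_ok = m[r0c, c0c] & m[r0c, c0c + 1] & m[r0c + 1, c0c] & m[r0c + 1, c0c + 1]
    mask = inside & support_ok
    out[~mask] = 0.0
    return RasterLayer(target, out, layer.units, mask)


def clip_tropics(
    layer: RasterLayer,
    lat_north: float = TROPIC_LAT,
    lat_south: float = -TROPIC_LAT,
) -> RasterLayer:
    """Mask cells whose center latitude lies outside the tropical band.

    The band is a closed interval: a center at exactly ±23.44° is retained.
    """
    lat = layer.grid.lat_centers()
    keep = (lat >= lat_south) & (lat <= lat_north)
    mask = layer.mask & keep[:, None]
    return RasterLayer(layer.grid, layer.values.copy(), layer.units, mask)


def tropics_band_mask(grid: GridSpec,
                      lat_north: float = TROPIC_LAT,
                      lat_south: float = -TROPIC_LAT) -> np.ndarray:
    """Boolean array: True where the cell center lies inside the closed band."""
    lat = grid.lat_centers()
    keep = (lat >= lat_south) & (lat <= lat_north)
    return np.broadcast_to(keep[:, None], grid.shape).copy()


def cell_area_ha(grid: GridSpec, constant_area: bool = False) -> RasterLayer:
    """Per-cell surface area in hectares on a sphere.

    area = R² · Δλ · (sin φ_top − sin φ_bottom), constant within a row and
    strictly decreasing with |latitude|. With ``constant_area=True`` every
    cell gets the equatorial-row value (nominal fixed-area convention).
    """
    dlam = math.radians(grid.cell_size)
    i = np.arange(grid.n_rows, dtype=np.float64)
    lat_top = np.radians(grid.origin_lat - i * grid.cell_size)
    lat_bot = np.radians(grid.origin_lat - (i + 1) * grid.cell_size)
    area_m2 = EARTH_RADIUS_M**2 * dlam * (np.sin(lat_top) - np.sin(lat_bot))
    if constant_area:
        dphi = math.radians(grid.cell_size)
        eq = EARTH_RADIUS_M**2 * dlam * 2 * math.sin(dphi / 2)
        area_m2 = np.full_like(area_m2, eq)
    vals = np.repeat((area_m2 / 1e4)[:, None], grid.n_cols, axis=1)
    return RasterLayer(grid, vals, units="ha")


# ---------------------------------------------------------------------------
# Zones
# ---------------------------------------------------------------------------


@dataclass
class Zone:
    zone_id: str
    region_id: str
    geometry: shapely.Geometry


@dataclass
class ZoneSet:
    """An ordered set of (multi)polygon zones with unique ids."""

    zones: list[Zone]

    def __post_init__(self) -> None:
        ids = [z.zone_id for z in self.zones]
        if len(set(ids)) != len(ids):
            raise ValueError("zone_ids must be unique")

    def __iter__(self):
        return iter(self.zones)

    def __len__(self) -> int:
        return len(self.zones)

    def assign_cells(self, grid: GridSpec) -> np.ndarray:
        """Zone index per cell by the cell-center rule, -1 where unassigned.

        A center on a shared border goes to the first zone in file order.
        """
        lon, lat = np.meshgrid(grid.lon_centers(), grid.lat_centers())
        assignment = np.full(grid.shape, -1, dtype=np.int64)
        for k, zone in enumerate(self.zones):
            hit = shapely.intersects_xy(zone.geometry, lon, lat)
            assignment[(assignment == -1) & hit] = k
        return assignment


def zonal_sum(layer: RasterLayer, zones: ZoneSet) -> dict[str, float]:
    """Sum of unmasked cell values per zone (cell-center-in-polygon rule)."""
    assignment = zones.assign_cells(layer.grid)
    out: dict[str, float] = {}
    for k, zone in enumerate(zones):
        sel = (assignment == k) & layer.mask
        if not sel.any():
            warnings.warn(f"zone {zone.zone_id!r} contains no cell centers",
                          stacklevel=2)
            out[zone.zone_id] = 0.0
        else:
            out[zone.zone_id] = float(layer.values[sel].sum())
    return out


__all__ = [
    "EARTH_RADIUS_M",
    "TROPIC_LAT",
    "DEFAULT_CELL_SIZE",
    "GridSpec",
    "RasterLayer",
    "GridMismatchError",
    "Zone",
    "ZoneSet",
    "resample_bilinear",
    "clip_tropics",
    "tropics_band_mask",
    "cell_area_ha",
    "zonal_sum",
]
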