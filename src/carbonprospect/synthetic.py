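"""Seeded synthetic worlds for end-to-end testing of the pipeline.

A world bundles every input the pipeline consumes — biomass and its
per-cell standard deviation, topsoil organic carbon, categorical land
cover, projected deforestation fraction, recent-loss and settlement masks,
land rent, a country partition and project polygons with noisy issued-credit
series — together with a per-cell scalar *truth oracle* written
independently of the raster pipeline, so pipeline outputs can be checked
cell by cell against plain arithmetic.

Structural realism is the goal, not statistical realism: fields are
spatially autocorrelated (moving-average smoothed white noise), biomass is
lognormal and positive, deforestation risk is Beta-distributed and bounded,
countries are nearest-seed (Voronoi) partitions so zonal conservation can be
tested exactly, and credit series are multiplicative-lognormal transforms of
ground truth. Identical seeds give bit-identical worlds (PCG64, a fixed
algorithm, drives all randomness).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .certification import CertParams, EligibilityConfig, ThreatLayer
from .finance import FinanceParams
from .grid import GridSpec, RasterLayer, Zone, ZoneSet, cell_area_ha
from .pools import PoolParams
from .validation import ProjectRecord

#: Land-cover codes used by the generator (a small ESA-CCI-like legend).
LC_FOREST_EVERGREEN = 50
LC_FOREST_DECIDUOUS = 60
LC_AGRICULTURE = 10
LC_SAVANNA = 120
LC_URBAN = 190
LC_WATER = 210
ELIGIBLE_CODES = frozenset({LC_FOREST_EVERGREEN, LC_FOREST_DECIDUOUS})
INELIGIBLE_CODES = (LC_AGRICULTURE, LC_SAVANNA, LC_URBAN, LC_WATER)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a synthetic tropical-forest world.

    Defaults emulate a ~1 km tropical forest landscape: mean aboveground
    biomass 150 t/ha with 50% spatial CV and a 30% per-cell measurement SD,
    topsoil carbon 60 tC/ha moderately coupled to biomass, projected 15-year
    deforestation averaging ~17% (Beta(1.2, 6)), 30% of land in non-forest
    cover, sparse recent-loss (5%) and settlement (2%) masks, and land rent
    averaging $30/ha/yr.
    """

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 0.00833
    origin_lon: float = -60.0
    origin_lat: float | None = None   # default: band centered on the equator
    seed: int = 0
    correlation_length: int = 5       # cells
    agb_mean: float = 150.0           # t/ha
    agb_cv: float = 0.5
    agb_sd_frac: float = 0.3          # per-cell SD as fraction of AGB
    soc_mean: float = 60.0            # tC/ha
    soc_corr: float = 0.5
    defor_alpha: float = 1.2
    defor_beta: float = 6.0
    frac_ineligible_lc: float = 0.3
    frac_recent_loss: float = 0.05
    frac_settlement: float = 0.02
    n_countries: int = 6
    n_regions: int = 3
    n_projects: int = 10
    vcu_noise_cv: float = 0.3
    rent_mean: float = 30.0           # $/ha/yr
    rent_cv: float = 1.0
    horizon_years: int = 15

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("degenerate config: zero-size grid")
        for name in ("frac_ineligible_lc", "frac_recent_loss", "frac_settlement"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if min(self.agb_mean, self.soc_mean, self.rent_mean) <= 0:
            raise ValueError("field means must be positive")

    def grid(self) -> GridSpec:
        lat0 = self.origin_lat
        if lat0 is None:
            lat0 = self.n_rows * self.cell_size / 2.0
        return GridSpec(self.origin_lon, lat0, self.cell_size,
                        self.n_rows, self.n_cols)


@dataclass
class SynthWorld:
    """All pipeline inputs plus the generator's ground truth hooks."""

    config: SynthConfig
    grid: GridSpec
    agb: RasterLayer
    agb_sd: RasterLayer
    soc: RasterLayer
    landcover: RasterLayer
    d_total: RasterLayer
    recent_loss: RasterLayer
    settlements: RasterLayer
    rent: RasterLayer
    zones: ZoneSet
    projects: list[ProjectRecord]
    eligible_in_band: np.ndarray = field(repr=False, default=None)  # type: ignore

    def threat(self) -> ThreatLayer:
        return ThreatLayer(self.d_total, horizon_years=self.config.horizon_years)

    def eligibility_config(self) -> EligibilityConfig:
        return EligibilityConfig(ELIGIBLE_CODES, self.recent_loss, self.settlements)

    def area(self) -> RasterLayer:
        return cell_area_ha(self.grid)

    def truth(self, row: int, col: int,
              pool_params: PoolParams = PoolParams(),
              cert: CertParams = CertParams(),
              fin: FinanceParams = FinanceParams()) -> dict[str, dict[str, float]]:
        """Scalar truth oracle at one cell (see :func:`truth_oracle`)."""
        area = self.area().values[row, col]
        return truth_oracle(
            agb=float(self.agb.values[row, col]),
            agb_sd=float(self.agb_sd.values[row, col]),
            soc=float(self.soc.values[row, col]),
            d_total=float(self.d_total.values[row, col]),
            eligible=bool(self.eligible_in_band[row, col]),
            area_ha=float(area),
            horizon_years=self.config.horizon_years,
            pool_params=pool_params, cert=cert, fin=fin,
        )


# ---------------------------------------------------------------------------
# The scalar truth oracle
# ---------------------------------------------------------------------------


def truth_oracle(agb: float, agb_sd: float, soc: float, d_total: float,
                 eligible: bool, area_ha: float,
                 horizon_years: int = 15,
                 pool_params: PoolParams = PoolParams(),
                 cert: CertParams = CertParams(),
                 fin: FinanceParams = FinanceParams()) -> dict[str, dict[str, float]]:
    """Single-cell investible flux and NPV by straightforward scalar math.

    A from-first-principles reimplementation of the whole per-cell chain
    (pools -> certification -> pricing), kept deliberately free of the
    raster code so the two routes can be cross-checked. Returns
    ``{"flux_fast": {...}, "flux_slow": {...}, "flux_total": {...},
    "npv": {...}}``, each keyed low/central/high.
    """
    p = pool_params
    d_annual = d_total / horizon_years
    keep = 1.0 - cert.buffer_fraction
    elig = 1.0 if eligible else 0.0

    def bgb(x: float) -> tuple[float, float]:
        # np.power on a float64 scalar is the same IEEE primitive the raster
        # path applies elementwise, keeping the two routes bit-comparable
        return (p.allom1_coef * float(np.power(np.float64(x), p.allom1_exp)),
                p.allom2_coef * x)

    agb_lo = max(agb - agb_sd, 0.0)
    agb_hi = agb + agb_sd
    e1c, e2c = bgb(agb)
    e1l, e2l = bgb(agb_lo)
    e1h, e2h = bgb(agb_hi)
    tracks = {
        "low": (agb_lo * p.stoich_low * p.co2_factor,
                min(e1l, e2l) * p.stoich_low * p.co2_factor),
        "central": (agb * p.stoich_central * p.co2_factor,
                    (e1c + e2c) / 2.0 * p.stoich_central * p.co2_factor),
        "high": (agb_hi * p.stoich_high * p.co2_factor,
                 max(e1h, e2h) * p.stoich_high * p.co2_factor),
    }
    soc_co2 = soc * p.co2_factor

    out: dict[str, dict[str, float]] = {
        "flux_fast": {}, "flux_slow": {}, "flux_total": {}, "npv": {}}
    for name, (agc, bgc) in tracks.items():
        dens_fast = keep * d_annual * (agc + soc_co2) * elig
        dens_slow = keep * d_annual * bgc * elig
        ff = dens_fast * area_ha
        fs = dens_slow * area_ha
        out["flux_fast"][name] = ff
        out["flux_slow"][name] = fs
        out["flux_total"][name] = ff + fs

        npv = -fin.establishment_cost * fin.cost_multiplier * area_ha
        for t in range(1, fin.horizon + 1):
            price = fin.price0 if t <= fin.flat_years else (
                fin.price0 * (1.0 + fin.appreciation) ** (t - fin.flat_years))
            q = ff + fs * min(t, cert.bgc_decay_years) / cert.bgc_decay_years
            cash = price * q - fin.maintenance_cost * fin.cost_multiplier * area_ha
            npv += cash / (1.0 + fin.discount) ** t
        out["npv"][name] = npv
    return out


# ---------------------------------------------------------------------------
# Field generators
# ---------------------------------------------------------------------------


def _smoothed_standard_field(rng: np.random.Generator, shape: tuple[int, int],
                             corr: int) -> np.ndarray:
    """Moving-average smoothed white noise, standardized to mean 0, sd 1."""
    white = rng.standard_normal(shape)
    if corr > 1:
        white = ndimage.uniform_filter(white, size=corr, mode="nearest")
    return (white - white.mean()) / white.std()


def _lognormal_field(rng: np.random.Generator, shape, corr: int,
                     mean: float, cv: float) -> np.ndarray:
    """Positive autocorrelated field rescaled to the exact target mean."""
    z = _smoothed_standard_field(rng, shape, corr)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    vals = np.exp(sigma * z)
    return vals * (mean / vals.mean())


def _exact_fraction_mask(rng: np.random.Generator, shape, frac: float) -> np.ndarray:
    """Binary mask with an exact cell count (round(frac * n) ones)."""
    n = shape[0] * shape[1]
    k = int(round(frac * n))
    mask = np.zeros(n, dtype=bool)
    if k:
        mask[rng.choice(n, size=k, replace=False)] = True
    return mask.reshape(shape)


def _voronoi_zones(rng: np.random.Generator, grid: GridSpec,
                   n_countries: int, n_regions: int) -> ZoneSet:
    """Nearest-seed country partition of the grid bounding box."""
    w, s, e, n = grid.bounds()
    xs = rng.uniform(w, e, size=n_countries)
    ys = rng.uniform(s, n, size=n_countries)
    seeds = [shapely.Point(x, y) for x, y in zip(xs, ys)]
    bbox = shapely.box(w, s, e, n)
    cells = shapely.get_parts(
        shapely.voronoi_polygons(shapely.MultiPoint(seeds), extend_to=bbox))
    # voronoi output order is arbitrary; map polygons back to their seeds
    order = np.argsort(xs, kind="stable")
    region_of = {int(k): f"region_{int(i * n_regions / n_countries)}"
                 for i, k in enumerate(order)}
    zones = []
    for k, seed in enumerate(seeds):
        poly = next(c for c in cells if c.covers(seed))
        zones.append(Zone(zone_id=f"country_{k:02d}",
                          region_id=region_of[k],
                          geometry=poly.intersection(bbox)))
    return ZoneSet(zones)


def generate_world(config: SynthConfig = SynthConfig()) -> SynthWorld:
    """Generate a complete synthetic world; identical seeds are bit-identical."""
    grid = config.grid()
    shape = grid.shape
    rng = np.random.Generator(np.random.PCG64(config.seed))

    agb_vals = _lognormal_field(rng, shape, config.correlation_length,
                                config.agb_mean, config.agb_cv)
    agb = RasterLayer(grid, agb_vals, units="t/ha")
    agb_sd = RasterLayer(grid, config.agb_sd_frac * agb_vals, units="t/ha")

    soc_base = agb_vals / agb_vals.mean() * config.soc_mean
    soc_resid = _lognormal_field(rng, shape, config.correlation_length,
                                 config.soc_mean, 0.4)
    soc_vals = np.maximum(
        config.soc_corr * soc_base + (1.0 - config.soc_corr) * soc_resid, 0.0)
    soc = RasterLayer(grid, soc_vals, units="tC/ha")

    d_raw = rng.beta(config.defor_alpha, config.defor_beta, size=shape)
    if config.correlation_length > 1:
        d_raw = ndimage.uniform_filter(d_raw, size=config.correlation_length,
                                       mode="nearest")
    d_total = RasterLayer(grid, np.clip(d_raw, 0.0, 1.0), units="fraction")

    # land cover: threshold a smooth field so the ineligible share is exact
    lc_field = _smoothed_standard_field(rng, shape, config.correlation_length)
    n_cells = shape[0] * shape[1]
    k_inelig = int(round(config.frac_ineligible_lc * n_cells))
    inelig_sel = _smoothed_pick(lc_field, k_inelig)
    lc_vals = np.where(
        rng.random(shape) < 0.5, float(LC_FOREST_EVERGREEN), float(LC_FOREST_DECIDUOUS))
    lc_vals[inelig_sel] = rng.choice(
        np.asarray(INELIGIBLE_CODES, dtype=np.float64), size=int(inelig_sel.sum()))
    landcover = RasterLayer(grid, lc_vals, units="code")

    recent = _exact_fraction_mask(rng, shape, config.frac_recent_loss)
    settle = _exact_fraction_mask(rng, shape, config.frac_settlement)
    recent_loss = RasterLayer(grid, recent.astype(np.float64), units="0/1")
    settlements = RasterLayer(grid, settle.astype(np.float64), units="0/1")

    rent_vals = _lognormal_field(rng, shape, config.correlation_length,
                                 config.rent_mean, config.rent_cv)
    rent = RasterLayer(grid, rent_vals, units="$/ha/yr")

    zones = _voronoi_zones(rng, grid, config.n_countries, config.n_regions)

    lat = grid.lat_centers()
    in_band = (lat >= -23.44) & (lat <= 23.44)
    eligible = (np.isin(lc_vals, list(ELIGIBLE_CODES))
                & (recent_loss.values == 0) & (settlements.values == 0)
                & in_band[:, None])

    world = SynthWorld(config=config, grid=grid, agb=agb, agb_sd=agb_sd,
                       soc=soc, landcover=landcover, d_total=d_total,
                       recent_loss=recent_loss, settlements=settlements,
                       rent=rent, zones=zones, projects=[],
                       eligible_in_band=eligible)
    world.projects = _generate_projects(rng, world)
    return world


def _smoothed_pick(field_vals: np.ndarray, k: int) -> np.ndarray:
    """Boolean selection of the k smallest values of a field (exact count)."""
    sel = np.zeros(field_vals.size, dtype=bool)
    if k:
        sel[np.argsort(field_vals, axis=None, kind="stable")[:k]] = True
    return sel.reshape(field_vals.shape)


def _generate_projects(rng: np.random.Generator,
                       world: SynthWorld) -> list[ProjectRecord]:
    """Random rectangular projects over eligible cells with noisy VCU series.

    Issued credits per vintage are the footprint's summed truth flux
    (central track) times multiplicative lognormal noise with the configured
    CV; zero CV reproduces the truth exactly.
    """
    cfg = world.config
    grid = world.grid
    area = world.area().values
    elig_rc = np.argwhere(world.eligible_in_band)
    projects: list[ProjectRecord] = []
    if elig_rc.shape[0] == 0 or cfg.n_projects == 0:
        return projects

    cv = cfg.vcu_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    lon_c = grid.lon_centers()
    lat_c = grid.lat_centers()
    for k in range(cfg.n_projects):
        r, c = elig_rc[rng.integers(elig_rc.shape[0])]
        half_r = int(rng.integers(2, 7))
        half_c = int(rng.integers(2, 7))
        r0, r1 = max(r - half_r, 0), min(r + half_r, grid.n_rows - 1)
        c0, c1 = max(c - half_c, 0), min(c + half_c, grid.n_cols - 1)
        # box spans the outer edges of the covered cells
        geom = shapely.box(lon_c[c0] - grid.cell_size / 2,
                           lat_c[r1] - grid.cell_size / 2,
                           lon_c[c1] + grid.cell_size / 2,
                           lat_c[r0] + grid.cell_size / 2)
        hit = np.zeros(grid.shape, dtype=bool)
        hit[r0:r1 + 1, c0:c1 + 1] = True
        flux_truth = np.zeros(grid.shape)
        for i, j in np.argwhere(hit):
            flux_truth[i, j] = world.truth(i, j)["flux_total"]["central"]
        # summed with the same boolean-index order the pipeline's zonal sum uses
        model_truth = flux_truth[hit].sum()

        n_vintages = int(rng.integers(1, 11))
        series = []
        for v in range(n_vintages):
            noise = math.exp(sigma * rng.standard_normal()
                             - sigma * sigma / 2.0) if cv > 0 else 1.0
            series.append((2009 + v, float(model_truth * noise)))
        projects.append(ProjectRecord(project_id=f"proj_{k:02d}",
                                      geometry=geom, vcu_series=series))
    return projects


# ---------------------------------------------------------------------------
# World bundle I/O
# ---------------------------------------------------------------------------

_RASTER_FIELDS = ("agb", "agb_sd", "soc", "landcover", "d_total",
                  "recent_loss", "settlements", "rent")


def write_world(world: SynthWorld, outdir: str | Path) -> None:
    """Write the world as a GeoTIFF + GeoJSON + CSV bundle with a manifest."""
    from .io import write_geotiff, write_zones_geojson

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _RASTER_FIELDS:
        write_geotiff(out / f"{name}.tif", getattr(world, name))
    write_zones_geojson(out / "zones.geojson", world.zones)

    features = [
        {"type": "Feature",
         "properties": {"project_id": p.project_id},
         "geometry": json.loads(shapely.to_geojson(p.geometry))}
        for p in world.projects
    ]
    (out / "projects.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": features}))
    rows = [{"project_id": p.project_id, "vintage_year": y, "vcu_tco2e": v}
            for p in world.projects for y, v in p.vcu_series]
    pd.DataFrame(rows, columns=["project_id", "vintage_year", "vcu_tco2e"]) \
        .to_csv(out / "vcu_series.csv", index=False)
    manifest = {"config": dataclasses.asdict(world.config),
                "eligible_codes": sorted(ELIGIBLE_CODES)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_world(indir: str | Path) -> SynthWorld:
    """Re-load a world bundle written by :func:`write_world`."""
    from shapely.geometry import shape as geojson_shape

    from .io import read_geotiff, read_zones_geojson

    ind = Path(indir)
    manifest = json.loads((ind / "manifest.json").read_text())
    config = SynthConfig(**manifest["config"])
    layers = {name: read_geotiff(ind / f"{name}.tif") for name in _RASTER_FIELDS}
    zones = read_zones_geojson(ind / "zones.geojson")

    vcu = pd.read_csv(ind / "vcu_series.csv", float_precision="round_trip")
    fc = json.loads((ind / "projects.geojson").read_text())
    projects = []
    for f in fc["features"]:
        pid = f["properties"]["project_id"]
        sub = vcu[vcu["project_id"] == pid]
        series = [(int(y), float(v))
                  for y, v in zip(sub["vintage_year"], sub["vcu_tco2e"])]
        projects.append(ProjectRecord(pid, geojson_shape(f["geometry"]), series))

    grid = layers["agb"].grid
    lat = grid.lat_centers()
    in_band = (lat >= -23.44) & (lat <= 23.44)
    eligible = (np.isin(layers["landcover"].values, list(ELIGIBLE_CODES))
                & (layers["recent_loss"].values == 0)
                & (layers["settlements"].values == 0)
                & in_band[:, None])
    return SynthWorld(config=config, grid=grid, zones=zones, projects=projects,
                      eligible_in_band=eligible, **layers)


__all__ = [
    "ELIGIBLE_CODES",
    "INELIGIBLE_CODES",
    "SynthConfig",
    "SynthWorld",
    "truth_oracle",
    "generate_world",
    "write_world",
    "read_world",
]
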