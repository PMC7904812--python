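"""Validation against issued verified carbon units (VCUs).

A project's modeled investible carbon is the zonal sum of central-track
investible flux over the cells whose centers fall inside the project
polygon. That single annual model value is paired against each of the
project's annual VCU issuances (1-10 vintages per project), and the pooled
pairs are compared with three statistics: Pearson's correlation, root mean
square error, and a paired t-test (two-sided, n - 1 degrees of freedom).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .certification import InvestibleFlux
from .grid import RasterLayer


class EmptyFootprintError(ValueError):
    """Project polygon contains no grid cell centers."""


@dataclass
class ProjectRecord:
    project_id: str
    geometry: shapely.Geometry
    vcu_series: list[tuple[int, float]]  # (vintage_year, issued tCO2e/yr)

    def __post_init__(self) -> None:
        years = [y for y, _ in self.vcu_series]
        if years != sorted(set(years)):
            raise ValueError("vintage years must be strictly increasing")
        if any(v < 0 for _, v in self.vcu_series):
            raise ValueError("issued VCUs must be non-negative")


@dataclass(frozen=True)
class ComparisonStats:
    n: int
    pearson_r: float
    rmse: float
    t_stat: float
    p_value: float

    @property
    def df(self) -> int:
        return self.n - 1


def project_model_estimate(investible: InvestibleFlux,
                           project: ProjectRecord,
                           buffered: bool = True) -> float:
    """Modeled annual investible carbon (tCO2/yr) inside the project polygon.

    Sums central-track flux over cells whose centers fall in the polygon
    (boundary centers included). ``buffered=False`` rescales to the
    pre-buffer certifiable flux.
    """
    layer: RasterLayer = investible.flux_total().central
    grid = layer.grid
    lon, lat = np.meshgrid(grid.lon_centers(), grid.lat_centers())
    hit = shapely.intersects_xy(project.geometry, lon, lat)
    if not hit.any():
        raise EmptyFootprintError(
            f"empty footprint: project {project.project_id!r} contains no cell centers")
    total = float(layer.values[hit & layer.mask].sum())
    if not buffered:
        total /= (1.0 - investible.params.buffer_fraction)
    return total


def pair_projects(investible: InvestibleFlux,
                  projects: list[ProjectRecord],
                  buffered: bool = True) -> pd.DataFrame:
    """One row per (project, vintage): the constant model estimate is
    repeated against each annual VCU observation."""
    rows = []
    for p in projects:
        est = project_model_estimate(investible, p, buffered=buffered)
        for year, vcu in p.vcu_series:
            rows.append({"project_id": p.project_id, "vintage_year": year,
                         "model": est, "vcu": vcu})
    return pd.DataFrame(rows)


def compare(pairs: list[tuple[float, float]] | pd.DataFrame) -> ComparisonStats:
    """Pearson r, RMSE and paired t between modeled and issued carbon.

    The degenerate all-equal case (every difference zero) is defined as
    t = 0, p = 1; a constant series makes r undefined and raises.
    """
    if isinstance(pairs, pd.DataFrame):
        model = pairs["model"].to_numpy(dtype=np.float64)
        vcu = pairs["vcu"].to_numpy(dtype=np.float64)
    else:
        arr = np.asarray(pairs, dtype=np.float64)
        model, vcu = arr[:, 0], arr[:, 1]
    n = model.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(model)) and np.all(np.isfinite(vcu))):
        raise ValueError("pairs must be finite")

    mx, my = model.mean(), vcu.mean()
    dx, dy = model - mx, vcu - my
    sxx, syy = (dx * dx).sum(), (dy * dy).sum()
    if sxx == 0 or syy == 0:
        raise ValueError("undefined correlation: one series is constant")
    r = float((dx * dy).sum() / math.sqrt(sxx * syy))

    rmse = float(np.sqrt(np.mean((model - vcu) ** 2)))

    d = model - vcu
    sd = float(d.std(ddof=1))
    md = float(d.mean())
    if sd == 0:
        if md != 0:
            raise ValueError("degenerate paired t: constant nonzero difference")
        t, p = 0.0, 1.0
    else:
        t = md / (sd / math.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return ComparisonStats(n=n, pearson_r=r, rmse=rmse, t_stat=float(t), p_value=p)


__all__ = [
    "EmptyFootprintError",
    "ProjectRecord",
    "ComparisonStats",
    "project_model_estimate",
    "pair_projects",
    "compare",
]
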