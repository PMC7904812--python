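"""Discounted cash-flow pricing of investible forest carbon.

A forest-protection project is priced over a 30-year horizon: an
establishment cost of $25/ha is paid at year 0 (undiscounted), maintenance
of $10/ha/yr and credit revenue arrive at the end of each year t = 1..30 and
are discounted at a 10%/yr risk-adjusted rate. The carbon price is $5.8/tCO2
for the first five years and appreciates 5%/yr thereafter:

    price(t) = price0                                  for t <= 5
    price(t) = price0 * (1 + g)^(t - 5)                for t  > 5

Credited volume in year t is flux_fast + flux_slow * min(t, D)/D with
D = 10 decay years for the belowground pool (tranche ramp), so revenue is
proportional to price0 and NPV is affine in price0 and in each flux
component. The break-even starting price therefore has the closed form
PV(costs) / PV(revenue at price0 = 1).

A cell is financially viable when its central-track NPV is strictly
positive. "Annualized NPV" is total 30-year NPV divided by the horizon —
a reporting convention, the total is always carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .certification import CertParams, InvestibleFlux
from .grid import GridSpec, RasterLayer, ZoneSet, _check_compatible
from .pools import Triple

#: Starting carbon prices ($/tCO2) for the sensitivity sweep.
DEFAULT_PRICE_GRID = (1.0, 5.0, 10.0, 15.0, 25.0, 50.0, 100.0)


@dataclass(frozen=True)
class FinanceParams:
    establishment_cost: float = 25.0   # $/ha at t=0
    maintenance_cost: float = 10.0     # $/ha/yr, t=1..horizon
    price0: float = 5.8                # $/tCO2 starting price
    flat_years: int = 5
    appreciation: float = 0.05         # per yr after the flat period
    horizon: int = 30                  # yr
    discount: float = 0.10             # per yr
    cost_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if min(self.establishment_cost, self.maintenance_cost, self.price0) < 0:
            raise ValueError("costs and prices must be non-negative")
        if not (0 < self.discount < 1):
            raise ValueError("discount must be in (0, 1)")
        if self.flat_years > self.horizon:
            raise ValueError("flat_years must not exceed horizon")

    def with_price0(self, price0: float) -> "FinanceParams":
        return replace(self, price0=price0)

    def with_cost_multiplier(self, m: float) -> "FinanceParams":
        return replace(self, cost_multiplier=m)


def price_at_year(t: int, params: FinanceParams = FinanceParams()) -> float:
    """Carbon price ($/tCO2) received at year t (1-based)."""
    if not 1 <= t <= params.horizon:
        raise ValueError(f"year {t} outside 1..{params.horizon}")
    if t <= params.flat_years:
        return params.price0
    return params.price0 * (1.0 + params.appreciation) ** (t - params.flat_years)


# ---------------------------------------------------------------------------
# The year-loop engine
# ---------------------------------------------------------------------------


def pv_revenue_unit(flux_fast, flux_slow,
                    params: FinanceParams, cert: CertParams):
    """PV of revenue at price0 = 1, by the year loop.

    Revenue scales linearly with price0, so PV(revenue) =
    price0 * pv_revenue_unit.
    """
    ff = np.asarray(flux_fast, dtype=np.float64)
    fs = np.asarray(flux_slow, dtype=np.float64)
    unit = params.with_price0(1.0)
    out = np.zeros(np.broadcast(ff, fs).shape, dtype=np.float64)
    for t in range(1, params.horizon + 1):
        q = ff + fs * min(t, cert.bgc_decay_years) / cert.bgc_decay_years
        out = out + price_at_year(t, unit) * q / (1.0 + params.discount) ** t
    return out


def pv_costs(area_ha, params: FinanceParams):
    """PV of establishment (t=0) plus maintenance (t=1..horizon) costs."""
    area = np.asarray(area_ha, dtype=np.float64)
    m = params.cost_multiplier
    out = params.establishment_cost * m * area
    for t in range(1, params.horizon + 1):
        out = out + params.maintenance_cost * m * area / (1.0 + params.discount) ** t
    return out


def npv_per_cell(flux_fast, flux_slow, area_ha,
                 params: FinanceParams = FinanceParams(),
                 cert: CertParams = CertParams()):
    """Net present value ($) of protecting the cell for the full horizon.

    Accepts scalars or co-shaped arrays; the year loop is vectorized over
    cells.
    """
    for name, x in (("flux_fast", flux_fast), ("flux_slow", flux_slow),
                    ("area_ha", area_ha)):
        arr = np.asarray(x, dtype=np.float64)
        if np.any(arr < 0):
            raise ValueError(f"{name} must be non-negative")
    npv = (params.price0 * pv_revenue_unit(flux_fast, flux_slow, params, cert)
           - pv_costs(area_ha, params))
    return float(npv) if np.ndim(npv) == 0 else npv


def break_even_price0(flux_fast, flux_slow, area_ha,
                      params: FinanceParams = FinanceParams(),
                      cert: CertParams = CertParams()):
    """Starting price ($/tCO2) at which NPV is exactly zero.

    Closed form PV(costs) / PV(revenue at price0 = 1); cells with zero flux
    get +inf (never viable at any price).
    """
    rev1 = pv_revenue_unit(flux_fast, flux_slow, params, cert)
    cost = pv_costs(area_ha, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        be = np.where(rev1 > 0, cost / np.where(rev1 > 0, rev1, 1.0), np.inf)
    return float(be) if np.ndim(be) == 0 else be


# ---------------------------------------------------------------------------
# Map-level products
# ---------------------------------------------------------------------------


@dataclass
class NPVMap:
    npv_total: Triple            # $/cell over the horizon
    npv_annualized: Triple       # $/cell/yr = npv_total / horizon
    viable: RasterLayer          # 0/1, central npv > 0
    break_even_price0: RasterLayer   # $/tCO2, central track

    @property
    def grid(self) -> GridSpec:
        return self.viable.grid

    def viable_only(self) -> Triple:
        """NPV with non-viable cells masked out (figure convention)."""
        ok = self.viable.values > 0

        def cut(layer: RasterLayer) -> RasterLayer:
            return RasterLayer(layer.grid, layer.values.copy(), layer.units,
                               layer.mask & ok)

        return self.npv_total.map(cut)


def npv_map(investible: InvestibleFlux, area: RasterLayer,
            params: FinanceParams = FinanceParams(),
            cert: CertParams | None = None) -> NPVMap:
    """Per-cell NPV, viability and break-even price from the certified flux."""
    cert = investible.params if cert is None else cert
    grid = investible.grid
    _check_compatible(grid, area.grid)

    totals, annuals = [], []
    cost = pv_costs(area.values, params)
    for ff, fs in zip(investible.flux_fast, investible.flux_slow):
        mask = ff.mask & fs.mask & area.mask
        rev1 = pv_revenue_unit(ff.values, fs.values, params, cert)
        npv = params.price0 * rev1 - cost
        totals.append(RasterLayer(grid, npv, units="$", mask=mask))
        annuals.append(RasterLayer(grid, npv / params.horizon, units="$/yr", mask=mask))
    npv_total = Triple(*totals)
    c = npv_total.central
    viable = RasterLayer(grid, (c.values > 0).astype(np.float64), "0/1", c.mask.copy())
    be = break_even_price0(investible.flux_fast.central.values,
                           investible.flux_slow.central.values,
                           area.values, params, cert)
    be_layer = RasterLayer(grid, be, units="$/tCO2", mask=c.mask.copy())
    return NPVMap(npv_total=npv_total,
                  npv_annualized=Triple(*annuals),
                  viable=viable,
                  break_even_price0=be_layer)


def price_sweep(investible: InvestibleFlux, area: RasterLayer,
                params: FinanceParams = FinanceParams(),
                cert: CertParams | None = None,
                price_grid: tuple[float, ...] = DEFAULT_PRICE_GRID) -> pd.DataFrame:
    """Viable carbon / area fractions as a function of the starting price.

    All other assumptions (flat period, appreciation, costs, discount) are
    held fixed; NPV is affine in price0 so each cell flips viable exactly at
    its break-even price. A cell sitting exactly at break-even (NPV = 0)
    counts as not viable.
    """
    if len(price_grid) == 0:
        raise ValueError("price_grid must not be empty")
    if any(p <= 0 for p in price_grid) or list(price_grid) != sorted(price_grid):
        raise ValueError("price_grid must be positive and sorted")
    cert = investible.params if cert is None else cert
    _check_compatible(investible.grid, area.grid)

    cost = pv_costs(area.values, params)
    rows = []
    track_data = {}
    for name, ff, fs in zip(("low", "central", "high"),
                            investible.flux_fast, investible.flux_slow):
        mask = ff.mask & fs.mask & area.mask
        total = ff.values + fs.values
        rev1 = pv_revenue_unit(ff.values, fs.values, params, cert)
        investible_cells = mask & (total > 0)
        track_data[name] = (rev1, total, investible_cells)

    for p in price_grid:
        row: dict[str, float] = {"price0": p}
        for name, (rev1, total, inv) in track_data.items():
            viable = inv & (p * rev1 - cost > 0)
            carbon_all = total[inv].sum()
            area_all = area.values[inv].sum()
            row[f"viable_carbon_fraction_{name}"] = (
                total[viable].sum() / carbon_all if carbon_all > 0 else 0.0)
            row[f"viable_area_fraction_{name}"] = (
                area.values[viable].sum() / area_all if area_all > 0 else 0.0)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["viable_carbon_fraction"] = df["viable_carbon_fraction_central"]
    df["viable_area_fraction"] = df["viable_area_fraction_central"]
    return df


def accumulation_curve(investible: InvestibleFlux, area: RasterLayer,
                       params: FinanceParams = FinanceParams(),
                       cert: CertParams | None = None,
                       zones: ZoneSet | None = None) -> pd.DataFrame:
    """Cumulative discounted profit of viable cells, per year and zone.

    Viability (central track) fixes the cell set; the low/high columns apply
    that same set to the low/high flux tracks. Year 0 carries the
    (negative) establishment outlay; the year-30 value of each track equals
    the aggregate NPV of the viable cells.
    """
    cert = investible.params if cert is None else cert
    nmap = npv_map(investible, area, params, cert)
    viable = nmap.viable.values > 0

    if zones is None:
        groups: list[tuple[str, np.ndarray]] = [("global", np.ones(investible.grid.shape, bool))]
    else:
        assignment = zones.assign_cells(investible.grid)
        groups = [(z.zone_id, assignment == k) for k, z in enumerate(zones)]

    rows = []
    for zone_id, inzone in groups:
        for name, ff, fs in zip(("low", "central", "high"),
                                investible.flux_fast, investible.flux_slow):
            sel = inzone & viable & ff.mask & fs.mask & area.mask
            ffs = ff.values[sel].sum()
            fss = fs.values[sel].sum()
            a = area.values[sel].sum()
            m = params.cost_multiplier
            cum = -params.establishment_cost * m * a
            rows.append({"zone_id": zone_id, "track": name, "year": 0,
                         "cumulative_profit": cum})
            for t in range(1, params.horizon + 1):
                q = ffs + fss * min(t, cert.bgc_decay_years) / cert.bgc_decay_years
                cash = (price_at_year(t, params) * q
                        - params.maintenance_cost * m * a)
                cum += cash / (1.0 + params.discount) ** t
                rows.append({"zone_id": zone_id, "track": name, "year": t,
                             "cumulative_profit": cum})
    return pd.DataFrame(rows)


__all__ = [
    "DEFAULT_PRICE_GRID",
    "FinanceParams",
    "NPVMap",
    "price_at_year",
    "pv_revenue_unit",
    "pv_costs",
    "npv_per_cell",
    "break_even_price0",
    "npv_map",
    "price_sweep",
    "accumulation_curve",
]
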