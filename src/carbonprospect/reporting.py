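"""Country/region/global summary tables.

The investible-carbon column sums the certified flux over all eligible
cells; the NPV column sums annualized NPV over financially viable cells
only (the map-figure convention). Region rows are sums of their country
rows and the global row is the sum of the region rows, so conservation
holds to machine precision before any rounding. Published values are
rounded to the nearest 1000 at emission time only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .certification import InvestibleFlux
from .finance import NPVMap
from .grid import ZoneSet


def round_thousand(x: float) -> float:
    """Round to the nearest 1000 (presentation only)."""
    return float(np.round(x / 1000.0) * 1000.0)


def _check_partition(zones: ZoneSet, grid) -> np.ndarray:
    lon, lat = np.meshgrid(grid.lon_centers(), grid.lat_centers())
    import shapely

    counts = np.zeros(grid.shape, dtype=np.int64)
    assignment = np.full(grid.shape, -1, dtype=np.int64)
    for k, z in enumerate(zones):
        hit = shapely.contains_xy(z.geometry, lon, lat)
        counts += hit
        assignment[(assignment == -1) & hit] = k
    if (counts > 1).any():
        raise ValueError("zones overlap: summary requires a partition")
    # boundary centers (contains misses them) fall back to first-covers
    if (assignment == -1).any():
        assignment = zones.assign_cells(grid)
    return assignment


def summarize(investible: InvestibleFlux, npv: NPVMap,
              zones: ZoneSet) -> pd.DataFrame:
    """Per-country rows with regional and global roll-ups (full precision).

    Columns: investible carbon (tCO2/yr) and annualized NPV ($/yr), each
    with an uncertainty column equal to the half-range of the low/high
    ensemble tracks.
    """
    grid = investible.grid
    assignment = _check_partition(zones, grid)
    total = investible.flux_total()
    viable = npv.viable.values > 0

    def sums(k: int) -> dict[str, float]:
        inzone = assignment == k
        out = {}
        for name, layer in zip(("low", "central", "high"), total):
            out[f"carbon_{name}"] = float(layer.values[inzone & layer.mask].sum())
        for name, layer in zip(("low", "central", "high"), npv.npv_annualized):
            sel = inzone & viable & layer.mask
            out[f"npv_{name}"] = float(layer.values[sel].sum())
        return out

    rows = []
    region_acc: dict[str, dict[str, float]] = {}
    for k, z in enumerate(zones):
        s = sums(k)
        rows.append({"region": z.region_id, "country": z.zone_id, **s})
        acc = region_acc.setdefault(z.region_id, dict.fromkeys(s, 0.0))
        for key, v in s.items():
            acc[key] += v

    out_rows = []
    glob = None
    for region in sorted(region_acc):
        acc = region_acc[region]
        out_rows.append({"region": region, "country": "(all)", **acc})
        if glob is None:
            glob = dict.fromkeys(acc, 0.0)
        for key, v in acc.items():
            glob[key] += v
    out_rows = [{"region": "(global)", "country": "(all)", **(glob or {})}] + \
        out_rows + rows

    df = pd.DataFrame(out_rows)
    df["investible_tco2_yr"] = df["carbon_central"]
    df["investible_unc"] = (df["carbon_high"] - df["carbon_low"]) / 2.0
    df["npv_usd_yr"] = df["npv_central"]
    df["npv_unc"] = (df["npv_high"] - df["npv_low"]) / 2.0
    return df


def emit_table(df: pd.DataFrame) -> pd.DataFrame:
    """Presentation copy with values rounded to the nearest 1000."""
    out = df[["region", "country", "investible_tco2_yr", "investible_unc",
              "npv_usd_yr", "npv_unc"]].copy()
    for col in out.columns[2:]:
        out[col] = out[col].map(round_thousand)
    return out


__all__ = ["round_thousand", "summarize", "emit_table"]
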