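"""Scenario analyses over the baseline pipeline.

Four risk levers are explored:

* **leakage** — protection displaces some deforestation beyond the project
  border; a leakage fraction L scales every flux component by (1 − L);
* **cost inflation** — establishment and maintenance costs scaled by a
  common multiplier (1.5x, 2.0x);
* **extra buffer** — the 20% non-permanence withhold raised by an extra
  10/20/30 points, re-running certification;
* **opportunity cost** — cells where the NPV of foregone land rent (a
  constant-rent annuity over the same horizon and discount rate) meets or
  exceeds the carbon NPV are excluded.

Each scenario recomputes viability from scratch, so cells pushed below
break-even are lost on top of the pure scaling effect. Reports give
profitable carbon (sum of investible flux over viable cells) and its percent
of the baseline profitable volume, for the low/central/high tracks; the
baseline denominator is held fixed across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .certification import CertParams, InvestibleFlux, certify
from .finance import FinanceParams, NPVMap, npv_map
from .grid import RasterLayer, _check_compatible
from .pools import CarbonPoolStack

BASE_BUFFER = 0.20


@dataclass(frozen=True)
class ScenarioConfig:
    label: str
    leakage_fraction: float = 0.0
    cost_multiplier: float = 1.0
    extra_buffer: float = 0.0
    opportunity_filter: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.leakage_fraction < 1):
            raise ValueError("leakage_fraction must be in [0, 1)")
        if self.cost_multiplier < 1:
            raise ValueError("cost_multiplier must be >= 1")
        if self.leakage_fraction + BASE_BUFFER + self.extra_buffer >= 1:
            raise ValueError("leakage plus effective buffer must stay below 1")


def apply_leakage(investible: InvestibleFlux, L: float) -> InvestibleFlux:
    """Scale every flux component by (1 − L)."""
    if not (0 <= L < 1):
        raise ValueError("leakage fraction must be in [0, 1)")
    return investible.scaled(1.0 - L)


def apply_extra_buffer(cert: CertParams, delta: float) -> CertParams:
    """Raise the non-permanence buffer by ``delta`` (additive)."""
    new_buffer = cert.buffer_fraction + delta
    if not (0 <= new_buffer < 1):
        raise ValueError("buffer_fraction + delta must stay in [0, 1)")
    return cert.with_buffer(new_buffer)


def opportunity_cost_filter(npv: NPVMap, rent: RasterLayer,
                            area: RasterLayer,
                            params: FinanceParams) -> RasterLayer:
    """0/1 keep-mask: keep iff carbon NPV (central) strictly exceeds rent NPV.

    Rent is capitalized as a constant real annuity over the same horizon and
    discount rate; ties are excluded (strict inequality).
    """
    _check_compatible(npv.grid, rent.grid)
    _check_compatible(npv.grid, area.grid)
    if np.any(rent.values[rent.mask] < 0):
        raise ValueError("rent must be non-negative")
    r = params.discount
    annuity = (1.0 - (1.0 + r) ** -params.horizon) / r
    npv_rent = rent.values * area.values * annuity
    keep = npv.npv_total.central.values > npv_rent
    mask = npv.viable.mask & rent.mask & area.mask
    return RasterLayer(npv.grid, keep.astype(np.float64), units="0/1", mask=mask)


@dataclass
class ScenarioReport:
    label: str
    profitable_carbon: dict[str, float]      # tCO2/yr, keys low/central/high
    percent_of_baseline: dict[str, float]    # %, same keys
    viable_area_ha: float


def _profitable_carbon(investible: InvestibleFlux, nmap: NPVMap,
                       area: RasterLayer,
                       keep: np.ndarray | None = None) -> tuple[dict, float]:
    viable = nmap.viable.values > 0
    if keep is not None:
        viable = viable & keep
    total = investible.flux_total()
    out = {}
    for name, layer in zip(("low", "central", "high"), total):
        sel = viable & layer.mask
        out[name] = float(layer.values[sel].sum())
    sel = viable & total.central.mask & area.mask
    return out, float(area.values[sel].sum())


def run_scenarios(
    pools: CarbonPoolStack,
    d_annual: RasterLayer,
    elig_mask: RasterLayer,
    area: RasterLayer,
    configs: list[ScenarioConfig],
    params: FinanceParams = FinanceParams(),
    cert: CertParams = CertParams(),
    rent: RasterLayer | None = None,
) -> list[ScenarioReport]:
    """Recompute certification, pricing and viability under each scenario.

    The first returned report is always the baseline; scenario percentages
    are relative to the baseline's central/low/high profitable carbon.
    """
    def evaluate(cfg: ScenarioConfig | None):
        c = cert if cfg is None else apply_extra_buffer(cert, cfg.extra_buffer)
        inv = certify(pools, d_annual, elig_mask, area, c)
        if cfg is not None and cfg.leakage_fraction:
            inv = apply_leakage(inv, cfg.leakage_fraction)
        p = params if cfg is None else params.with_cost_multiplier(
            params.cost_multiplier * cfg.cost_multiplier)
        nmap = npv_map(inv, area, p, c)
        keep = None
        if cfg is not None and cfg.opportunity_filter:
            if rent is None:
                raise ValueError("opportunity_filter requires a rent layer")
            keep = opportunity_cost_filter(nmap, rent, area, p).values > 0
        return _profitable_carbon(inv, nmap, area, keep)

    base_carbon, base_area = evaluate(None)
    reports = [ScenarioReport("baseline", base_carbon,
                              {k: 100.0 for k in base_carbon}, base_area)]
    for cfg in configs:
        carbon, varea = evaluate(cfg)
        pct = {k: (100.0 * carbon[k] / base_carbon[k] if base_carbon[k] > 0 else 0.0)
               for k in carbon}
        reports.append(ScenarioReport(cfg.label, carbon, pct, varea))
    return reports


def reports_to_frame(reports: list[ScenarioReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"scenario": r.label, "viable_area_ha": r.viable_area_ha}
        for k in ("low", "central", "high"):
            row[f"profitable_tCO2_yr_{k}"] = r.profitable_carbon[k]
            row[f"pct_of_baseline_{k}"] = r.percent_of_baseline[k]
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "BASE_BUFFER",
    "ScenarioConfig",
    "ScenarioReport",
    "apply_leakage",
    "apply_extra_buffer",
    "opportunity_cost_filter",
    "run_scenarios",
    "reports_to_frame",
]
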