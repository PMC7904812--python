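"""Certification rules: additionality, eligibility and the buffer withhold.

Only carbon under credible threat of loss is creditable (additionality).
The threat proxy is a projected fraction of each cell's forest lost over a
fixed horizon (15 years by default), annualized by simple proration
``d_annual = d_total / horizon``; a compound annualization
``1 − (1 − d_total)^(1/horizon)`` is available as an option.

Eligibility excludes land-cover classes that preclude forest (savanna, bare
ground, water, agriculture, urban), recently deforested cells, settlement
cells, and anything outside the tropical band.

Of the certifiable flux, a 20% non-permanence buffer is withheld; the
remainder is investible. The belowground pool's avoided emission is issued in
10 equal annual tranches (a ramp over the first decade) rather than
immediately — credit timing, not credit reduction — so the flux is split into
a fast (aboveground + soil) and a slow (belowground) component and the
finance stage applies the ramp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .grid import GridSpec, RasterLayer, _check_compatible, tropics_band_mask
from .pools import CarbonPoolStack, Triple

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThreatLayer:
    """Projected fraction of forest lost over ``horizon_years``, in [0, 1]."""

    d_total: RasterLayer
    horizon_years: int = 15

    def __post_init__(self) -> None:
        v = self.d_total.values[self.d_total.mask]
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("d_total must lie in [0, 1]")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")


@dataclass(frozen=True)
class EligibilityConfig:
    eligible_landcover_codes: frozenset[int]
    recent_loss: RasterLayer
    settlements: RasterLayer

    def __post_init__(self) -> None:
        for name, layer in (("recent_loss", self.recent_loss),
                            ("settlements", self.settlements)):
            v = layer.values[layer.mask]
            if v.size and not np.all(np.isin(v, (0.0, 1.0))):
                raise ValueError(f"{name} must be binary")


@dataclass(frozen=True)
class CertParams:
    buffer_fraction: float = 0.20
    bgc_decay_years: int = 10
    compound_annualization: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.buffer_fraction < 1):
            raise ValueError("buffer_fraction must be in [0, 1)")
        if self.bgc_decay_years < 1:
            raise ValueError("bgc_decay_years must be >= 1")

    def with_buffer(self, buffer_fraction: float) -> "CertParams":
        return replace(self, buffer_fraction=buffer_fraction)


@dataclass
class InvestibleFlux:
    """Per-cell annual investible CO2 (tCO2/cell/yr), buffered and masked.

    ``flux_fast`` covers the aboveground + soil pools (credited in the year
    the loss is avoided); ``flux_slow`` the belowground pool (issued on the
    decay-year ramp). ``density_fast/slow`` are the per-hectare companions.
    """

    flux_fast: Triple
    flux_slow: Triple
    density_fast: Triple
    density_slow: Triple
    eligibility: RasterLayer
    params: CertParams

    @property
    def grid(self) -> GridSpec:
        return self.flux_fast.central.grid

    def flux_total(self) -> Triple:
        return Triple(
            low=self.flux_fast.low + self.flux_slow.low,
            central=self.flux_fast.central + self.flux_slow.central,
            high=self.flux_fast.high + self.flux_slow.high,
        )

    def scaled(self, factor: float) -> "InvestibleFlux":
        """Every flux and density component scaled by ``factor``."""
        return InvestibleFlux(
            flux_fast=self.flux_fast.map(lambda l: l * factor),
            flux_slow=self.flux_slow.map(lambda l: l * factor),
            density_fast=self.density_fast.map(lambda l: l * factor),
            density_slow=self.density_slow.map(lambda l: l * factor),
            eligibility=self.eligibility,
            params=self.params,
        )


def annualize_deforestation(threat: ThreatLayer,
                            compound: bool = False) -> RasterLayer:
    """Annual deforestation fraction from the horizon total.

    Simple proration ``d_total / horizon`` by default; with
    ``compound=True``, the rate r solving (1−r)^horizon = 1 − d_total.
    """
    d = threat.d_total
    if compound:
        vals = 1.0 - np.power(1.0 - d.values, 1.0 / threat.horizon_years)
    else:
        vals = d.values / threat.horizon_years
    return RasterLayer(d.grid, vals, units="1/yr", mask=d.mask.copy())


def eligibility_mask(landcover: RasterLayer,
                     config: EligibilityConfig) -> RasterLayer:
    """0/1 layer: 1 iff the cell can host a certifiable forest project.

    Requires an eligible land-cover code, no recent deforestation, no
    settlement, and a cell center inside the tropical band. Codes absent
    from the eligible set are ineligible (and logged once).
    """
    _check_compatible(landcover.grid, config.recent_loss.grid)
    _check_compatible(landcover.grid, config.settlements.grid)
    codes = np.unique(landcover.values[landcover.mask]).astype(np.int64)
    unknown = [c for c in codes if c not in config.eligible_landcover_codes]
    if unknown:
        logger.info("treating land-cover codes %s as ineligible", unknown)
    eligible_code = np.isin(landcover.values, list(config.eligible_landcover_codes))
    ok = (
        eligible_code
        & (config.recent_loss.values == 0)
        & (config.settlements.values == 0)
        & tropics_band_mask(landcover.grid)
    )
    mask = landcover.mask & config.recent_loss.mask & config.settlements.mask
    return RasterLayer(landcover.grid, ok.astype(np.float64), units="0/1", mask=mask)


def certify(
    pools: CarbonPoolStack,
    d_annual: RasterLayer,
    mask: RasterLayer,
    area: RasterLayer,
    params: CertParams = CertParams(),
) -> InvestibleFlux:
    """Turn pool densities into buffered, eligibility-masked investible flux.

    Per track: density_fast = (1−buffer)·d_annual·(agc + soc) and
    density_slow = (1−buffer)·d_annual·bgc, both tCO2/ha/yr; per-cell flux is
    density × area × eligibility. Ineligible cells get exactly zero flux but
    stay on the grid.
    """
    grid = pools.grid
    for other in (d_annual, mask, area):
        _check_compatible(grid, other.grid)
    dv = d_annual.values[d_annual.mask]
    if dv.size and (dv.min() < 0 or dv.max() > 1):
        raise ValueError("d_annual must lie in [0, 1]")

    keep = 1.0 - params.buffer_fraction
    elig = mask.values
    common = d_annual.mask & mask.mask & area.mask

    def tracks(front: Triple, back: Triple | None = None):
        dens, flux = [], []
        for i, lay in enumerate(front):
            pool_sum = lay.values if back is None else lay.values + list(back)[i].values
            m = common & lay.mask
            d_ha = keep * d_annual.values * pool_sum * elig
            dens.append(RasterLayer(grid, d_ha, units="tCO2/ha/yr", mask=m))
            flux.append(RasterLayer(grid, d_ha * area.values, units="tCO2/yr", mask=m))
        return Triple(*dens), Triple(*flux)

    density_fast, flux_fast = tracks(pools.agc_co2, pools.soc_co2)
    density_slow, flux_slow = tracks(pools.bgc_co2)
    return InvestibleFlux(
        flux_fast=flux_fast,
        flux_slow=flux_slow,
        density_fast=density_fast,
        density_slow=density_slow,
        eligibility=mask,
        params=params,
    )


__all__ = [
    "ThreatLayer",
    "EligibilityConfig",
    "CertParams",
    "InvestibleFlux",
    "annualize_deforestation",
    "eligibility_mask",
    "certify",
]
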