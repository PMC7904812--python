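"""Carbon pools: aboveground, belowground and soil CO2 densities.

Aboveground biomass (t/ha) is converted to carbon with a stoichiometric
factor (0.475 central; 0.45 and 0.50 bound the range used across carbon
accounting references) and to CO2 with the molar-mass factor 3.67.
Belowground biomass is predicted from aboveground biomass with two
root-to-shoot allometric relations,

    bgb = 0.489 · agb^0.89        (power law)
    bgb = 0.26  · agb             (fixed root:shoot ratio)

and the per-cell mean/min/max over the two predictions feed the central /
low / high tracks. Topsoil (0–30 cm) organic carbon density (tC/ha) is
credited as given, times 3.67; no soil uncertainty model is applied.

The uncertainty tracks form a deterministic worst/central/best ensemble:
the low track combines the low stoichiometric factor, the minimum allometric
prediction and agb − sd (clipped at zero); the high track the converse. The
half-range (high − low)/2 is the package's uncertainty proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, RasterLayer, _check_compatible

CO2_FACTOR = 3.67


@dataclass(frozen=True)
class PoolParams:
    stoich_central: float = 0.475
    stoich_low: float = 0.45
    stoich_high: float = 0.50
    co2_factor: float = CO2_FACTOR
    allom1_coef: float = 0.489
    allom1_exp: float = 0.89
    allom2_coef: float = 0.26

    def __post_init__(self) -> None:
        if not (0 < self.stoich_low <= self.stoich_central <= self.stoich_high < 1):
            raise ValueError("stoichiometric factors must satisfy 0 < low <= central <= high < 1")
        if self.co2_factor <= 1:
            raise ValueError("co2_factor must exceed 1")


@dataclass
class Triple:
    """Low/central/high ensemble of co-registered layers."""

    low: RasterLayer
    central: RasterLayer
    high: RasterLayer

    def __iter__(self):
        return iter((self.low, self.central, self.high))

    def map(self, fn) -> "Triple":
        return Triple(fn(self.low), fn(self.central), fn(self.high))

    def half_range(self) -> RasterLayer:
        return (self.high - self.low) * 0.5


@dataclass
class CarbonPoolStack:
    """Per-cell CO2 density (tCO2/ha) for the three pools, each as a
    low/central/high track."""

    agc_co2: Triple
    bgc_co2: Triple
    soc_co2: Triple

    @property
    def grid(self) -> GridSpec:
        return self.agc_co2.central.grid


def _validate_nonneg(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def agb_to_agc_co2(agb, s: float = 0.475, co2_factor: float = CO2_FACTOR):
    """Aboveground biomass (t/ha) -> aboveground CO2 density (tCO2/ha)."""
    arr = _validate_nonneg(agb, "aboveground biomass")
    out = arr * s * co2_factor
    return float(out) if np.isscalar(agb) else out


def bgb_from_agb(agb, params: PoolParams = PoolParams()):
    """Belowground biomass predictions from the two allometric relations.

    Returns ``(eq1, eq2, mean, min, max)`` where eq1 is the power law and
    eq2 the linear ratio, all in t/ha.
    """
    arr = _validate_nonneg(agb, "aboveground biomass")
    eq1 = params.allom1_coef * np.power(arr, params.allom1_exp)
    eq2 = params.allom2_coef * arr
    mean = (eq1 + eq2) / 2.0
    lo = np.minimum(eq1, eq2)
    hi = np.maximum(eq1, eq2)
    if np.isscalar(agb):
        return float(eq1), float(eq2), float(mean), float(lo), float(hi)
    return eq1, eq2, mean, lo, hi


def soc_to_co2(soc, co2_factor: float = CO2_FACTOR):
    """Topsoil organic carbon density (tC/ha) -> CO2 density (tCO2/ha)."""
    arr = _validate_nonneg(soc, "soil organic carbon")
    out = arr * co2_factor
    return float(out) if np.isscalar(soc) else out


def build_pool_stack(
    agb: RasterLayer,
    agb_sd: RasterLayer,
    soc: RasterLayer,
    params: PoolParams = PoolParams(),
) -> CarbonPoolStack:
    """Assemble the three-pool CO2 density stack with its uncertainty tracks.

    Track composition (aboveground and belowground pools):

    ========  ==============  =====================  =================
    track     stoich factor   allometric prediction  biomass input
    ========  ==============  =====================  =================
    low       0.45            cell-wise minimum      max(agb − sd, 0)
    central   0.475           mean of the two        agb
    high      0.50            cell-wise maximum      agb + sd
    ========  ==============  =====================  =================

    The soil pool is identical in all three tracks (soc × 3.67).
    """
    _check_compatible(agb.grid, agb_sd.grid)
    _check_compatible(agb.grid, soc.grid)
    _validate_nonneg(agb.values[agb.mask], "aboveground biomass")
    _validate_nonneg(agb_sd.values[agb_sd.mask], "aboveground biomass sd")
    _validate_nonneg(soc.values[soc.mask], "soil organic carbon")

    mask = agb.mask & agb_sd.mask & soc.mask
    f = params.co2_factor

    agb_lo = np.maximum(agb.values - agb_sd.values, 0.0)
    agb_hi = agb.values + agb_sd.values

    def layer(vals: np.ndarray) -> RasterLayer:
        return RasterLayer(agb.grid, vals, units="tCO2/ha", mask=mask.copy())

    agc = Triple(
        low=layer(agb_lo * params.stoich_low * f),
        central=layer(agb.values * params.stoich_central * f),
        high=layer(agb_hi * params.stoich_high * f),
    )
    _, _, bgb_c, _, _ = bgb_from_agb(agb.values, params)
    _, _, _, bgb_lo, _ = bgb_from_agb(agb_lo, params)
    _, _, _, _, bgb_hi = bgb_from_agb(agb_hi, params)
    bgc = Triple(
        low=layer(bgb_lo * params.stoich_low * f),
        central=layer(bgb_c * params.stoich_central * f),
        high=layer(bgb_hi * params.stoich_high * f),
    )
    soc_vals = soc.values * f
    soc_t = Triple(low=layer(soc_vals.copy()),
                   central=layer(soc_vals.copy()),
                   high=layer(soc_vals.copy()))
    return CarbonPoolStack(agc_co2=agc, bgc_co2=bgc, soc_co2=soc_t)


__all__ = [
    "CO2_FACTOR",
    "PoolParams",
    "Triple",
    "CarbonPoolStack",
    "agb_to_agc_co2",
    "bgb_from_agb",
    "soc_to_co2",
    "build_pool_stack",
]
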