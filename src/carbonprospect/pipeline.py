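"""End-to-end orchestration: world -> pools -> certification -> finance.

One call, :func:`run_pipeline`, chains every stage on a (synthetic or
loaded) world and returns all intermediate products, so the CLI, the
examples and the test suite share a single code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .certification import (CertParams, InvestibleFlux, annualize_deforestation,
                            certify, eligibility_mask)
from .finance import (DEFAULT_PRICE_GRID, FinanceParams, NPVMap,
                      accumulation_curve, npv_map, price_sweep)
from .grid import RasterLayer
from .pools import CarbonPoolStack, PoolParams, build_pool_stack
from .reporting import summarize
from .synthetic import SynthWorld


@dataclass
class PipelineResult:
    world: SynthWorld
    pools: CarbonPoolStack
    d_annual: RasterLayer
    eligibility: RasterLayer
    area: RasterLayer
    investible: InvestibleFlux
    npv: NPVMap
    summary: pd.DataFrame
    sweep: pd.DataFrame | None = None
    accumulation: pd.DataFrame | None = None


def run_pipeline(world: SynthWorld,
                 pool_params: PoolParams = PoolParams(),
                 cert: CertParams = CertParams(),
                 fin: FinanceParams = FinanceParams(),
                 with_sweep: bool = False,
                 with_accumulation: bool = False,
                 price_grid: tuple[float, ...] = DEFAULT_PRICE_GRID) -> PipelineResult:
    """Run pools, certification, pricing and the summary table on a world."""
    pools = build_pool_stack(world.agb, world.agb_sd, world.soc, pool_params)
    d_annual = annualize_deforestation(world.threat(),
                                       compound=cert.compound_annualization)
    elig = eligibility_mask(world.landcover, world.eligibility_config())
    area = world.area()
    investible = certify(pools, d_annual, elig, area, cert)
    nmap = npv_map(investible, area, fin, cert)
    summary = summarize(investible, nmap, world.zones)
    sweep = price_sweep(investible, area, fin, cert, price_grid) if with_sweep else None
    acc = accumulation_curve(investible, area, fin, cert) if with_accumulation else None
    return PipelineResult(world=world, pools=pools, d_annual=d_annual,
                          eligibility=elig, area=area, investible=investible,
                          npv=nmap, summary=summary, sweep=sweep,
                          accumulation=acc)


__all__ = ["PipelineResult", "run_pipeline"]
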