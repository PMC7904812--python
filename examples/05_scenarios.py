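"""Risk scenarios: leakage, cost inflation, extra buffer, opportunity cost.

Each scenario re-runs certification and pricing from scratch and reports
profitable carbon (flux summed over viable cells) as a percent of the
baseline, so threshold-crossing losses show up on top of pure scaling.
"""

import carbonprospect as cp
from carbonprospect.certification import annualize_deforestation, eligibility_mask

world = cp.generate_world(cp.SynthConfig(seed=1))
pools = cp.build_pool_stack(world.agb, world.agb_sd, world.soc)
d_annual = annualize_deforestation(world.threat())
elig = eligibility_mask(world.landcover, world.eligibility_config())

configs = [
    cp.ScenarioConfig("leakage 10%", leakage_fraction=0.1),
    cp.ScenarioConfig("leakage 20%", leakage_fraction=0.2),
    cp.ScenarioConfig("leakage 30%", leakage_fraction=0.3),
    cp.ScenarioConfig("costs x1.5", cost_multiplier=1.5),
    cp.ScenarioConfig("costs x2.0", cost_multiplier=2.0),
    cp.ScenarioConfig("buffer +10pp", extra_buffer=0.1),
    cp.ScenarioConfig("opportunity cost", opportunity_filter=True),
]
reports = cp.run_scenarios(pools, d_annual, elig, world.area(), configs,
                           rent=world.rent)
for r in reports:
    print(f"{r.label:>18s}: {r.profitable_carbon['central'] / 1e6:6.2f} "
          f"MtCO2/yr  ({r.percent_of_baseline['central']:5.1f}% of baseline)")
print("(percentages < pure scaling indicate cells pushed below break-even)")
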