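"""Convert biomass and soil inputs into three-pool CO2 densities.

Aboveground biomass becomes CO2 via the stoichiometric factor (0.475) and
the C-to-CO2 molar factor (3.67); belowground biomass comes from two
root-to-shoot allometric relations; topsoil carbon is credited as given.
Low/central/high tracks form a deterministic uncertainty ensemble.
"""

import carbonprospect as cp

# scalar conversions first: a cell with 100 t/ha of aboveground biomass
agb = 100.0
print(f"aboveground CO2 at {agb:.0f} t/ha biomass: "
      f"{cp.agb_to_agc_co2(agb):.3f} tCO2/ha")
eq1, eq2, mean, lo, hi = cp.bgb_from_agb(agb)
print(f"belowground biomass, power law: {eq1:.3f} t/ha; "
      f"fixed ratio: {eq2:.3f} t/ha; central (mean): {mean:.3f} t/ha")
print(f"soil CO2 at 50 tC/ha: {cp.soc_to_co2(50.0):.1f} tCO2/ha")

# the same conversions, raster-wide with the uncertainty ensemble
world = cp.generate_world(cp.SynthConfig(n_rows=80, n_cols=80, seed=7))
stack = cp.build_pool_stack(world.agb, world.agb_sd, world.soc)
for name, triple in (("aboveground", stack.agc_co2),
                     ("belowground", stack.bgc_co2),
                     ("soil", stack.soc_co2)):
    c = triple.central.values.mean()
    half = triple.half_range().values.mean()
    print(f"{name:>12s} pool: {c:7.1f} +/- {half:5.1f} tCO2/ha "
          f"(mean central +/- half-range)")
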