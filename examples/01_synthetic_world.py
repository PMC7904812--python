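"""Generate a seeded synthetic tropical-forest world and inspect its inputs.

The world bundles every raster the pipeline needs (biomass +/- SD, soil
carbon, land cover, projected deforestation, exclusion masks, land rent), a
country partition and mock carbon projects with noisy issued-credit series.
"""

import carbonprospect as cp

world = cp.generate_world(cp.SynthConfig(n_rows=120, n_cols=120, seed=42))

print(f"grid: {world.grid.n_rows}x{world.grid.n_cols} cells of "
      f"{world.grid.cell_size} deg (~1 km)")
print(f"aboveground biomass: mean {world.agb.values.mean():.1f} t/ha, "
      f"CV {world.agb.values.std() / world.agb.values.mean():.2f}")
print(f"topsoil organic carbon: mean {world.soc.values.mean():.1f} tC/ha")
print(f"projected 15-yr deforestation: mean "
      f"{world.d_total.values.mean():.3f} (fraction of each cell)")
print(f"countries: {len(world.zones)}, projects: {len(world.projects)}")

# Both numbers below are planted by the generator, so downstream stages can
# be checked against exact ground truth.
elig = cp.eligibility_mask(world.landcover, world.eligibility_config())
print(f"eligible (forest, unflagged, in-band) fraction: "
      f"{elig.values.mean():.3f}")
cell = world.truth(60, 60)
print(f"truth oracle at cell (60,60): investible flux "
      f"{cell['flux_total']['central']:.1f} tCO2/yr, "
      f"NPV ${cell['npv']['central']:,.0f}")
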