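"""Price sensitivity: how much carbon becomes viable as the price rises.

Repeats the viability analysis over starting prices $1..$100/tCO2 (all
other assumptions unchanged) and reports the viable share of investible
carbon and area -- the saturating curve that policy price floors move along.
"""

import carbonprospect as cp

world = cp.generate_world(cp.SynthConfig(seed=1))
res = cp.run_pipeline(world, with_sweep=True)

print("price0   viable carbon   viable area")
for _, row in res.sweep.iterrows():
    print(f"  ${row['price0']:5.0f}       {row['viable_carbon_fraction']:6.1%}"
          f"        {row['viable_area_fraction']:6.1%}")
print("(fractions of total investible carbon / area; monotone in price,"
      " saturating once every flux-positive cell clears break-even)")
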