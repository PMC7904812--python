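"""Certify investible carbon and price it with the 30-year cash-flow model.

Certification applies additionality (flux proportional to the annualized
deforestation threat), eligibility exclusions, and the 20% non-permanence
buffer. Finance discounts credit revenue ($5.8/tCO2 flat for 5 years, then
+5%/yr) against $25/ha establishment and $10/ha/yr maintenance at 10%/yr.
"""

import carbonprospect as cp

world = cp.generate_world(cp.SynthConfig(seed=1))
res = cp.run_pipeline(world)

total = res.investible.flux_total().central
print(f"investible carbon: {total.sum() / 1e6:.2f} MtCO2/yr over "
      f"{world.grid.n_rows * world.grid.n_cols} cells")
print(f"viable cells (NPV > 0): {res.npv.viable.values.mean():.1%}")

viable_npv = res.npv.viable_only().central
print(f"aggregate NPV of viable cells: "
      f"${viable_npv.values[viable_npv.mask].sum() / 1e6:,.1f}M over 30 yr")

# per-hectare worked numbers under the default parameters
pv_costs = -cp.npv_per_cell(0.0, 0.0, 1.0)
print(f"PV of costs per hectare: ${pv_costs:.2f}")
be_flux = cp.break_even_price0(1.0, 0.0, 1.0) / cp.FinanceParams().price0
print(f"break-even flux at $5.8/tCO2: {be_flux:.3f} tCO2/ha/yr")
be = res.npv.break_even_price0
import numpy as np
print(f"median break-even starting price on this world: "
      f"${np.median(be.values[np.isfinite(be.values)]):.2f}/tCO2")
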