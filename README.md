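# carbonprospect

**Carbon prospecting for avoided-deforestation projects**: map per-cell
investible forest carbon under Voluntary Carbon Standard (VCS) rules, price
it with a 30-year discounted cash-flow model, and derive viability maps,
break-even carbon prices, price-sensitivity curves, risk scenarios and
validation statistics against issued verified carbon units (VCUs).

The package is aimed at conservation-finance and carbon-accounting analysts
who want a transparent, fully testable implementation of the
"where is forest protection bankable?" calculation — from raw biomass/soil/
deforestation rasters to country-level tables — exercisable end to end on
seeded synthetic landscapes with known per-cell ground truth.

## The model

On a regular ~1 km lon/lat grid clipped to the tropics (±23.44°), each cell
carries three carbon pools (tCO₂/ha):

- **aboveground**: `AGC = AGB · s · 3.67`, with stoichiometric factor
  s = 0.475 (0.45 / 0.50 bounding the range used across accounting
  references);
- **belowground**, from two root-to-shoot allometries,
  `BGB = 0.489 · AGB^0.89` and `BGB = 0.26 · AGB`, mean/min/max per cell
  feeding the central/low/high tracks;
- **soil**: topsoil (0–30 cm) organic carbon × 3.67.

Certification turns stocks into an annual *investible flux*
(tCO₂ cell⁻¹ yr⁻¹):

```
flux = (1 − buffer) · d · (AGC + BGC + SOC) · area,   d = D/15
```

where D is the projected 15-year deforestation fraction (additionality:
no threat, no credit), ineligible cells (non-forest cover, recent loss,
settlements, outside the band) get exactly zero, and buffer = 20% is the
VCS non-permanence withhold. Belowground credits are issued on a 10-year
tranche ramp (credit timing, not reduction).

Finance discounts credit revenue — price $5.8/tCO₂ flat for 5 years, then
+5 %/yr — against $25/ha establishment (year 0) and $10/ha/yr maintenance,
at a 10 %/yr risk-adjusted rate over 30 years:

```
NPV = −E·A + Σ_{t=1..30} [ p(t)·q(t) − M·A ] / 1.1^t
```

A cell is *viable* if NPV > 0; because NPV is affine in the starting price,
each cell's **break-even price** has the closed form
PV(costs) / PV(revenue at price 1). Scenario layers (leakage, cost
inflation, extra buffer, opportunity-cost rent screening) and a validation
stage (Pearson r / RMSE / paired t against VCU issuances inside project
polygons) complete the pipeline.

## Worked example

```python
import carbonprospect as cp

world = cp.generate_world(cp.SynthConfig(seed=1))   # 200x200 synthetic tropics
res = cp.run_pipeline(world, with_sweep=True)

print(res.investible.flux_total().central.sum() / 1e6)  # MtCO2/yr
print(res.npv.viable.values.mean())                     # viable cell fraction
```

Running `python examples/03_certify_and_price.py` prints:

```
investible carbon: 10.88 MtCO2/yr over 40000 cells
viable cells (NPV > 0): 64.8%
aggregate NPV of viable cells: $511.7M over 30 yr
PV of costs per hectare: $119.27
break-even flux at $5.8/tCO2: 1.612 tCO2/ha/yr
median break-even starting price on this world: $2.17/tCO2
```

The first three numbers describe the synthetic landscape (10.88 Mt of
annual certifiable CO₂, of which the cells holding most of it clear
break-even at the default price). The last three are parameter-determined:
protecting one hectare costs $119.27 in present value, so a cell needs
about 1.61 tCO₂ ha⁻¹ yr⁻¹ of buffered flux to break even at $5.8/tCO₂.
The other scripts in `examples/` walk through world generation, pool
building, the price sweep, the scenario battery and VCU validation, each
printing and explaining its outputs.

A CLI mirrors the library for shell use — each stage reads its
predecessor's outputs from a run directory:

```bash
carbonprospect --outdir run --seed 1 all       # simulate ... report
carbonprospect --outdir run sweep              # re-run a single stage
```

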