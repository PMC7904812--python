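# Methods

This note records the scientific assumptions, parameter choices and
numerical conventions behind `carbonprospect`, and what the synthetic-data
tests do and do not demonstrate about real data.

## Spatial model

All layers live on a regular geographic (lon/lat, WGS84) grid with
north-up rows and cell-center registration; the default resolution is
0.00833° (~1 km at the equator). Grids are compatible for arithmetic only
when all fields match exactly, and masked (nodata) cells propagate
strictly through every operation — a masked operand always masks the
result. We chose strictness over imputation because silent fill values are
the classic raster-pipeline failure mode.

Cell areas use a spherical Earth of radius 6,371,000 m:
`area = R²·Δλ·(sin φ_top − sin φ_bottom)`, constant within a row. The
ellipsoidal correction is below 0.3 % at tropical latitudes, which is far
inside the uncertainty of every other input; a constant-area switch
(`cell_area_ha(..., constant_area=True)`) reproduces the nominal-1-km²
convention for sensitivity checks, since data sources rarely state which
convention they used.

The tropical band is the closed interval [−23.44°, 23.44°] on cell-center
latitude: a center at exactly ±23.44° is retained. Zonal statistics use the
cell-center-in-polygon rule (no area-weighted partial cells); a center on a
shared border is assigned to the first zone in file order. Both rules are
deterministic and checkable against a brute-force point-in-polygon loop,
which the tests do.

Bilinear resampling interpolates at target cell centers from the four
surrounding source centers and masks any target cell whose support is
incomplete or touches a masked source cell. It is exact for affine fields,
which provides its test oracle. It is intended for coarsening/registration
(source cell ≤ target cell), matching how finer-scaled inputs are brought
onto the analysis grid; aggregation-style upscaling is out of scope.

## Carbon pools and the uncertainty ensemble

Aboveground biomass (t/ha) converts to carbon with a stoichiometric factor
and to CO₂ with 3.67 (44/12). Belowground biomass is predicted from
aboveground by two allometric relations (power law `0.489·AGB^0.89` and
fixed ratio `0.26·AGB`); topsoil organic carbon (0–30 cm, tC/ha) is
credited as given. Three deterministic tracks compose the uncertainty
ensemble:

| track   | stoich | allometry        | biomass input      |
|---------|--------|------------------|--------------------|
| low     | 0.45   | cell-wise min    | max(AGB − SD, 0)   |
| central | 0.475  | mean of the two  | AGB                |
| high    | 0.50   | cell-wise max    | AGB + SD           |

The half-range (high − low)/2 is reported as the uncertainty proxy. This
worst/central/best composition is **not** a probabilistic error model: the
three sources (stoichiometry, allometry, measurement SD) are treated as
perfectly co-moving, so the half-range upper-bounds what independent
combination would give. The soil pool carries no uncertainty model and is
identical in all tracks. Negative low-track biomass is clipped at zero.

## Certification

Additionality is operationalised as flux proportional to the annualized
deforestation threat: `d = D/15` with D the projected 15-year loss
fraction. Simple proration is the default because the threat projections
are themselves linear extrapolations; the compound alternative
`1 − (1 − D)^(1/15)` is available (`CertParams(compound_annualization=True)`)
and is slightly larger for D ∈ (0, 1).

Eligibility requires a forest land-cover code, no recent deforestation, no
settlement, and a center inside the tropical band; unknown codes are
ineligible. Ineligible cells get exactly zero flux but stay on the grid so
that area bookkeeping is conserved.

The 20 % non-permanence buffer scales flux by (1 − buffer). The
"conservative 10-year decay" of the belowground pool is read as credit
*timing*: each year's avoided belowground emission is issued in 10 equal
annual tranches, so year-t belowground credit is `flux_slow·min(t,10)/10`.
This conserves total carbon while being strictly revenue-conservative in
the early years; crediting the full belowground flux immediately would
raise early revenue by at most the belowground share (~15–20 % of flux).
The soil pool is credited in full on deforestation, which may overstate
soil credits where mineralisation is partial.

## Finance

Cash-flow timing: establishment ($25/ha, times any cost multiplier) is
paid at year 0 undiscounted; maintenance ($10/ha/yr) and revenue arrive at
end-of-year t = 1..30 and discount by 1.1⁻ᵗ. The price schedule is
$5.8/tCO₂ for years 1–5 and +5 %/yr thereafter; a price sweep rescales the
whole schedule through the starting price with every other assumption
fixed. Since revenue is proportional to the starting price, NPV is affine
in it and the break-even starting price is the closed ratio
PV(costs)/PV(revenue at price 1), with +∞ for zero-flux cells. Viability
is *strictly* positive NPV; a cell exactly at break-even is not viable.
"Annualized NPV" is total NPV divided by the 30-year horizon — a reporting
convention only; the total is always carried alongside.

The engine is a vectorized year loop; the geometric-series
(annuity + growing annuity) closed form is kept in the tests as an
independent oracle and agrees to ≤ 1e-9 relative over 1,000 random
parameter draws. Break-even prices agree with bisection on the engine to
1e-6.

Accumulation curves fix the viable set from the central track and apply it
to all three flux tracks, so each track's year-30 value telescopes to that
track's aggregate NPV over the same cells.

## Scenarios

Leakage L scales every flux component by (1 − L); an extra buffer δ sets
the withhold to 0.2 + δ (algebraically identical to leakage when
(1 − L) = (1 − 0.2 − δ)/(1 − 0.2), which the tests cross-check); cost
multipliers scale establishment and maintenance jointly; the
opportunity-cost screen keeps a cell only when carbon NPV strictly exceeds
the rent NPV, with constant real rent capitalized by the same 30-year/10 %
annuity (ties excluded). Every scenario recomputes viability from scratch
so threshold-crossing cells are lost on top of pure scaling; percentages
are reported against the *baseline* profitable volume, a convention chosen
because the alternative (scenario-specific denominators) cannot be
compared across scenarios.

## Validation

A project's modeled value is the zonal sum of central-track investible
(i.e., post-buffer) flux over cells whose centers fall in its polygon, and
that single constant is paired against each of the project's annual VCU
issuances (1–10 vintages), pooling all pairs. Statistics: product-moment
Pearson r, RMSE, and a paired t with sample SD (n − 1) and two-sided
Student-t p-value. The all-differences-zero degenerate case is defined as
t = 0, p = 1 (perfect agreement must not error); a constant series makes r
undefined and raises. An unbuffered comparison switch
(`project_model_estimate(..., buffered=False)`) is provided because
registries report issuance after buffer withholding, but practice varies.

## Synthetic worlds

The generator emulates the *structure* of the real inputs, not their
statistics: spatially autocorrelated positive biomass (moving-average
smoothed Gaussian noise pushed through a lognormal transform, rescaled to
the exact target mean), soil carbon as a biomass-coupled mixture, Beta-
distributed smoothed deforestation risk in [0, 1], categorical land cover
with an exact ineligible share, exact-count sparse masks, lognormal rent,
Voronoi (nearest-seed) country partitions — a true partition, so zonal
conservation is testable exactly — and rectangular projects over eligible
cells whose VCU series are truth × lognormal noise. Defaults describe a
~1 km tropical forest landscape: AGB 150 t/ha (CV 0.5, per-cell SD 30 %),
SOC 60 tC/ha, 15-year deforestation ~17 % (Beta(1.2, 6)), 30 % non-forest
cover, 5 % recent loss, 2 % settlements, rent $30/ha/yr.

All randomness flows through a single PCG64 generator keyed by the config
seed — a fixed algorithm, so identical seeds give bit-identical worlds
across platforms.

Each world embeds a **scalar truth oracle**: a from-first-principles
single-cell reimplementation of pools → certification → pricing, kept free
of the raster code. Flux from the raster pipeline is bit-identical to the
oracle (the oracle calls the same IEEE pow primitive the array path uses,
so the two routes share no code but share arithmetic); NPV agrees to
≤ 1e-9 relative, the looser bound reflecting genuinely different summation
orders.

What passing these tests shows: the pipeline computes its stated model
exactly, conserves carbon and money through every aggregation, and
degrades monotonically under every risk lever. What it does not show:
anything about the realism of real-world biomass, threat or price inputs —
on real data the outputs inherit those inputs' biases wholesale.

## Problem sizes and numerical conventions

The standard study world is 200×200 cells (~40,000 km²); the end-to-end
determinism check runs 500×500. These sizes exercise every code path with
thousands of viable/non-viable cells on both sides of break-even while
keeping the full suite fast; all operations are vectorized and scale
linearly in cell count. All computation is double precision. Quantities
the design calls exact (buffer conservation, zonal partition sums,
sweep/break-even equivalence) are asserted at machine precision (≤ a few
ulp, since factors like 0.8 and 0.875 interact with rounding); engine-vs-
oracle agreements carry the explicit tolerances above. Summary tables keep
full precision internally; rounding to the nearest 1,000 happens only at
emission.

## Known limitations

- The uncertainty ensemble is a deterministic envelope, not a calibrated
  error model; half-ranges should be read as spans, not standard errors.
- Leakage is aspatial (a uniform fraction), with no displacement to named
  neighbouring cells.
- The threat layer is exogenous; protection does not feed back into
  neighbouring threat, and land cover is static over the horizon.
- Opportunity-cost screening assumes constant real rents.
- No reprojection between projected CRSs and no ellipsoidal geodesy;
  inputs must already be geographic lon/lat.
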