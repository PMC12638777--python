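# Methods

This note documents the models, the synthetic-landscape generator, the
numerical choices and the limitations of `nexusland`. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Suboptimal-cropland classification

Three criteria are combined as a union over cropland pixels (pure cropland
at full pixel area, mosaic cropland — assumed 50% crop / 50% non-crop
vegetation — at half):

* **Slope.** `slope_deg > 8` (strict; a pixel at exactly 8° is not
  suboptimal). The sensitivity sweep exposes 7° and 9°.
* **Fragmentation.** Default rule: a cropland pixel with no 8-connected
  cropland neighbour, approximating a <10 ha isolated patch at ~9 ha
  pixels. Either density class counts as a neighbour; a same-class-only
  reading is available behind `frag_same_class_only` because the verbal
  rule admits both. `frag_max_patch_px=2` switches to an 8-connected
  component rule (≈20 ha patches).
* **Low productivity.** Growing-season cumulative NDVI standardised over
  each subregion's cropland; pixels below a subregional z threshold are
  flagged. Thresholds live in [−2, −0.5]: subregions ranked by cropland
  abundance map to quantiles of a Normal(−1.25, 0.375) truncated to that
  interval, the least crop-abundant subregion receiving the threshold
  nearest −0.5. σ = 0.375 makes ±2σ span the interval; the exact
  distributional mechanics across subregions are our construction
  (quantile mapping), as the verbal description pins only the range,
  centre and rank direction. Degenerate subregions (zero NDVI variance or
  <2 cropland pixels) flag nothing — there is no information to rank.

Under near-normal NDVI this z-rule flags roughly Φ(threshold) ≈ 3–14% of
each subregion's cropland by construction, so on synthetic landscapes the
low-productivity class is a larger share of the suboptimal total (and the
slope class a smaller one, ~50–60%) than in continental applications where
NDVI distributions are heavier-tailed.

## Calorie accounting

Consumer-level calories follow the chain
`t × 1000 × dry_fraction × kcal_per_kg_dry × (1 − waste) × (1 − loss)`
with waste = 0.17 and per-crop loss factors from the crop-metadata CSV
(`src/nexusland/data/crop_metadata.csv`; dry fractions, calorie contents,
loss rates and fertilizer rates are representative European values chosen
once at design time). Vegetables and pulses are not mass-accounted;
their calorie supply is set to 10% of the cell's cereal + oil + sugar +
root calories and split by harvested area. Woody perennials carry no
calories and their cultivation is retained in every scenario.

Coarse-cell production is distributed over cropland pixels with the yield
weighting 1 : ½(1+ω) (pure : mosaic) — the "same productivity within a
coarse cell" assumption — while physical harvested area uses 1 : ½.
Summing downscaled pixel calories over any pixel set therefore evaluates
the cell-ratio loss formula exactly; the revegetation deficit is that sum
over all suboptimal cropland. Tagged retained-woody pixels are an *area*
designation: because woody crops carry no calories, the deficit is
unchanged by retention (the cereal share of those pixels is still
cleared).

## Mosaic yield effect (ω)

Per subregion, cell mean production per physical cropland hectare is
regressed (OLS, intercept suppressed) on the composition (1−f, f), f the
mosaic share of the cell's cropland area; ω = ŷ_m/ŷ_p − 1. Cells whose
cropland straddles subregion borders are excluded (purity > 0.999): they
mix different base yields and bias the fit. Subregions with fewer than
`n_min = 10` usable cells, or no composition variation, fall back to a
continental pooled estimate — a fixed-point fit with subregion-specific
base yields and one common ω. A fully unidentifiable effect (e.g. an
all-pure landscape) falls back to ω = 0 with a warning. Standard errors
use the delta method on the coefficient ratio.

At desk scale (~100 coarse cells) the estimate carries sampling noise of
roughly ±0.07 around the planted +9.5% across generator seeds; the
parameter-recovery suite shows that with pixel-level yield noise of 5% as
the only stochastic term (~50 cells per subregion) the estimate falls in
[0.075, 0.115] in ≥90% of 100 replicates.

## Scenario engine

Revegetation: each coarse cell's woody pixel-equivalent (woody area share
summed over its cropland pixels) is retained on its steepest suboptimal
pixels — woody perennials concentrate on steep, terraced land — capped at
the cell's suboptimal count; option N sends the rest to natural regrowth,
option NA regrows only inside biodiversity-priority or water-scarce areas
and afforests elsewhere.

Conversion: intensification candidates are mosaic pixels outside
biodiversity-priority, water-scarce and degradation-risk (≥2 of 12
critical processes) areas and below 800 m; extensification candidates are
all pure-cropland pixels, prioritised by the 8-tier constraint order
(B∧W∧D, B∧W, B∧D, W∧D, B, W, D, rest). Within a tier (and for I overall)
the order is NPCD descending (pure-cropland count in a 13 × 13 window,
centre excluded, computed on the pre-scenario map), then net calorie gain
descending, then row-major index — a deterministic total order. Only
pixels with strictly positive gain are candidates; the greedy prefix stops
at the first pixel whose inclusion reaches the deficit, converted in full
(no fractional conversion), so the compensation share can slightly exceed
1 and is reported honestly (<1) when candidates run out.

Gains: the switched crop is chosen per coarse cell (HC: highest consumer
calorie yield per hectare among the 11 switchable crops; HS: largest
current harvested area; ties break alphabetically). An intensified pixel
cultivates its full area minus the retained protected area at the switched
yield; an extensified pixel cultivates half its area minus protected at
the switched yield boosted by (1+ω). The protected crop groups
(vegetables, pulses, woody) keep their absolute area and calories on every
converted pixel. `harvest_rate` (default 1.0; 0.8 for the reduced-harvest
sensitivity case) scales switched-crop calories only.

## Carbon ledger

Canonical internal unit: t CO₂-eq yr⁻¹ per pixel (C→CO₂ via 44/12),
reported in Mt. Savings = regrowth (30-yr mean accumulation rate ×
area) + afforestation (max of coniferous/non-coniferous MAI × 1.2 branch
factor — MAI is stem-only) + mosaic planting (non-coniferous MAI × branch
factor × subregional tree cover × half pixel) + avoided N₂O (revegetated
suboptimal cropland and switched-off crops). Emissions = clearing
(pixel-mean non-crop AGBC oxidised, amortised over 30 yr; gaps filled
with the 13 × 13 mosaic-neighbour mean) + forestry operations (0.30 t
CO₂/ha on suboptimal cropland, 0.15 t CO₂/ha in mosaics, amortised over
the same 30 yr for comparability) + N₂O of newly planted switched crops.
The ledger identity net = savings − emissions holds at machine precision.
Net mosaic-planting flux is floored at zero (it is identically zero where
tree cover is zero). Soil organic carbon, belowground biomass and CH₄ are
out of scope.

Direct soil N₂O uses the exponential response
Y(x) = I(x) − I(0), I(x) = exp[((μ₀+σ₀²)²−μ₀²)/(2σ₀²)]·
exp[((μ₁+σ₁²x)²−μ₁²)/(2σ₁²)] (kg N₂O-N ha⁻¹ yr⁻¹, x in kg N ha⁻¹).
**The shipped μ₀ = −1.2, σ₀² = 0.8, μ₁ = 0.008, σ₁ = 0.0022 are synthetic
placeholders**, calibrated only to give plausible magnitudes (≈0.45 kg at
x = 0 rising to ≈2.5 kg at x = 200); fitted values must be supplied for
real-data use. Indirect N₂O uses the IPCC 2006 defaults (EF₄ = 0.010,
EF₅ = 0.0075, Frac_GASF = 0.10, Frac_LEACH = 0.30); the leaching pathway
applies under irrigation or where rainy-season P − PET exceeds the soil
water-holding capacity, rainy months being those wetter than one third of
the wettest month. N₂O-N converts by 44/28 and GWP₁₀₀ = 273 (configurable).

## Biodiversity pressure

Per-pixel loss = natural-vegetation richness minus the richness of the
actual state: pure cropland and intensified pixels at the cropland
richness layer; mosaic and extensified pixels at 130% of cropland richness
(CI 118.7–140.7%), capped at the natural benchmark by default (the
uncapped variant is a flag) so pressure is never negative; plantations at
71% of natural richness (CI 68–74%); regrowth restores natural richness;
retained woody cropland stays at cropland richness. Baseline mosaic
pixels use the same 130% rule so baseline and scenario are commensurable.
BI_CC (baseline) and BI_AC (scenario) are landscape sums; the reduction is
(BI_CC − BI_AC)/BI_CC. Uncertainty bounds re-run the accounting at the
factor CIs; carbon bounds scale savings and emissions by ±15% and pair
the lowest-bound savings with the highest-bound emissions (and vice
versa). The N-vs-NA trade-off is ΔB = (N − NA)/NA on the carbon or
biodiversity benefit.

## Synthetic landscape generator

Fields are frequency-domain-smoothed white noise (Gaussian transfer; the
correlation length parameterises the *output* autocorrelation, so L = 0.5
is near-white and L = 16 strongly smooth), class maps threshold one smooth
field at quantiles (realised fractions match requests to grid
discreteness), and subregions are a Voronoi partition of random points —
contiguous stand-ins for administrative subregions, not a claim of
equivalence. Slope and degradation fields are quantile-mapped to exact
marginals so planted tail fractions (share of steep terrain, degradation
counts) do not drift with the field realisation.

Deliberate statistical couplings mirror the study conditions rather than
independent noise:

* yields and NDVI share one productivity gradient and both fall off on
  slopes above 4° (4% per degree, floor 0.3), so suboptimal cropland is
  less productive than average and the low-productivity class overlaps
  steep terrain;
* degradation counts and biodiversity priority co-vary with steep terrain,
  so the suboptimal class overlaps the constraint masks substantially, as
  observed continentally;
* per-crop agro-ecological suitability is lognormal (σ = 0.7) per
  subregion while sown crop shares are drawn independently of it
  (wheat/barley-heavy Dirichlet), so the locally best switchable crop
  out-yields the present mix — the headroom that crop switching exploits
  and the reason highest-calorie switching can compensate the
  revegetation deficit where highest-suitability switching cannot.

Default conditions: 120 × 120 pixels of 9 ha, mosaic = 50% crop, true
ω = +9.5%, protected crops 15% of harvested area (6% vegetables, 3%
pulses, 6% woody), constraint prevalences 30% biodiversity / 10% water /
8% irrigated, 5% pixel yield noise, 10% smooth spatial yield variation.
The dataclass default `coarse_factor = 30` mirrors the 5-arc-min to 300 m
scale ratio; the standard test and acceptance landscapes use
`coarse_factor = 12` (100 coarse cells) because ω unmixing needs tens of
cells per subregion to be identifiable at desk scale.

What the generator does **not** emulate: satellite time-series artifacts,
real CRS geometry (pixel area is a scalar), heavy-tailed NDVI
distributions, spatially coherent national boundaries, markets or any
socio-economic structure. Passing tests demonstrate the correctness of
the accounting chain and the estimators on landscapes with these
statistical properties — not the continental magnitudes themselves, which
depend on the real data stack.

## Known desk-scale limitations

* The ω estimate on a single 100-cell landscape carries sampling noise of
  about ±0.07; continental applications pool orders of magnitude more
  cells.
* Highest-suitability (HS) switching rarely compensates fully on synthetic
  landscapes: with wheat locally dominant almost everywhere, the HS crop
  seldom clears the extensification break-even of ≈2.2× the current
  per-hectare calorie yield. The continental analogue compensates via
  regions where the dominant crop is also calorie-dense.
* A compensation share ≥1 for highest-calorie switching is a property of
  landscapes with sufficient suitability headroom; on a minority of
  generator seeds extensification falls short and the share is reported
  honestly below 1.
* N₂O magnitudes are placeholder-parameterised (above) and should not be
  interpreted quantitatively.
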