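# Methods

This note records the models, conventions and design choices behind
`lifecost`, in the spirit of a model-description chapter: what is computed,
under which assumptions, and what the synthetic worlds do and do not
establish about real data.

## 1. Extinction model and the restore layer

The core quantity is a per-cell *restore density*: the change in the
expected number of extinctions, summed over species, per km² of agricultural
land restored to natural habitat. For species `s` with current area of
habitat `A_s` and pristine (human-absent) area `A0_s`, extinction
probability follows the species–area power law

    p(A) = 1 − (A / A0)^z,        z > 0, default z = 0.25.

Restoring a cell changes `A_s` by `δA_s` and the density sums
`p(A_s) − p(A_s + δA_s)` over species, divided by the restored area. The
sign structure is determined by habitat suitability per land-cover class
(natural, cropland, pasture):

* natural suitable, agricultural cover not: `δA > 0`, positive contribution;
* both suitable, or neither: `δA = 0`, zero contribution — a species that
  tolerates farmland neither gains nor loses from restoration;
* only the agricultural cover suitable: `δA < 0`, negative contribution.

All species count equally, regardless of threat status; the layer therefore
scales with richness, endemism and accumulated habitat loss. Because
`p` is concave in `A` for `z < 1`, a fixed `δA` matters far more to a
narrow-ranged endemic than to a wide-ranged species — the property that
makes tropical, endemism-rich cells expensive.

The exact functional form used by the real restore layer is defined
upstream of this package; the power law here is an explicit emulation
choice with `z` configurable. Marginality is intrinsic: per-cell changes
are evaluated independently, and linear aggregation of the layer is only
trusted for land areas up to about 1,000 km² (Section 6).

## 2. Synthetic worlds

`generate_world(WorldConfig)` produces all layers and tables the analysis
needs, on an abstract equal-area grid (default 40×40 cells of 100 km²,
6 countries, 10 commodities of which 3 animal, 120 species). There is no
geographic CRS: removing projection and area-distortion logic keeps the
testable core exact; readers for real projected rasters would do area
weighting before data enters.

Choices a field scientist would recognise as "realistic in structure":

* **Land cover** per cell is a triple of area fractions (natural, cropland
  by commodity, pasture) summing to ≤ 1; agricultural fraction is drawn
  uniformly in [0.15, 0.6], so every cell keeps ≥ 0.4 natural cover and
  every species retains positive habitat.
* **Species** are rectangular-block ranges, a mixture of endemics
  (≤ 6 cells by default, 35% of species) and wide-rangers (30–70% of the
  grid span); 25% tolerate cropland, 35% pasture. With `tropics_gradient`
  range centres are drawn triangularly toward the high-row ("equatorial")
  edge, producing the within-grid gradient in restore density that mirrors
  the tropics-vs-temperate contrast in the real layer.
* **Yields** are role-specific national means (grains 4 t/ha, roots
  25 t/ha, sugar 50 t/ha, …) with lognormal country (σ=0.3) and cell
  (σ=0.15) variation. Energy densities and protein fractions are set per
  role at food-composition-table magnitudes (grain 3,400 kcal/kg @ 12%
  protein, ruminant meat 2,500 @ 26%, dairy 640 @ 3.4%, …).
* **Livestock** follow gridded-livestock-style density surfaces; ruminants
  (meat, dairy) occupy pasture, monogastrics any farmed land. Grazing
  requirements are *derived*, not drawn: pasture area is allocated among
  ruminant products by local density share and divided by production, so
  implied-land accounting closes by construction. Feed conversion totals
  are role-based (ruminant meat 5.0, poultry 2.2, dairy 0.7 kg feed per kg
  product) split over feed crops by a Dirichlet draw.
* **Tables balance exactly.** Bilateral trade is drawn from production
  (exports can never exceed supply), feed draw is capped at 80% of domestic
  supply of each feed crop, and food supply is the exact residual
  `P + imports − exports − feed`, with no stock term. Conservation
  invariants in the tests are therefore exact, not approximate.
* **Determinism.** All randomness flows from one seed; every generator
  stage draws from a named substream (`crc32(stage name)` mixed into the
  seed sequence), so adding draws to one stage cannot perturb another, and
  identical (config, seed) worlds serialise byte-identically.

Trade modes: `random` (default), `autarky` (T ≡ 0, used for the no-trade
identities), and `reexport_chain` (the last country produces none of the
first commodity but imports and re-exports it, exercising the re-export
correction's raison d'être).

What the generator does *not* emulate — and hence what green tests do not
show about real data: realistic biogeography and range shapes, IUCN habitat
coding, commodity trees deeper than one processing level, bilateral
asymmetries and stock changes in trade statistics, land-use intensity, and
the sheer heterogeneity of real yield surfaces. The tests establish that
the *accounting and statistics* are correct; magnitudes from synthetic
worlds are indicative only.

## 3. Weighted quantiles and national impacts

All aggregation uses a lower-value (type-1) weighted quantile with no
interpolation: the smallest value whose cumulative weight reaches
`q × total`. Rationale: it is invariant under weight rescaling, returns an
observed value, and is exactly reproduced by the expand-each-value-by-its-
integer-weight oracle, which the tests exploit. No interpolation rule is
standard in this literature, so the simplest exactly-testable convention
was chosen.

National production impacts are weighted medians of per-cell
`density × area / production_kg` over producing cells. Cell weights are
production mass by default; harvested area is available via configuration
(`cell_weighting="area"`) since either reading of "where the commodity is
produced" is defensible, and global weighting is unambiguously by mass.
Cells with nodata density are excluded from the median, not treated as
zero. A country producing none of a commodity yields *defined-absent*
(`None`), never zero — a zero would silently deflate global distributions.

Grazing aggregation uses the same weighted-median convention with livestock
density as weights (`grazing_aggregation="mean"` is available); consistency
with the crop aggregation was preferred over the unknowable real choice.

## 4. Re-export correction

The provenance fixed point is solved as one dense linear system
`(I − M) F = diag(P/s)` with `M[i,j] = T[j→i]/s_i`, after dropping
zero-supply countries (with a warning). The system is strictly diagonally
dominant whenever every trading country retains some domestic production
or supply, and singular exactly for pure re-export cycles with no
production anywhere — reported as an error, not a result. An iterative
flow-propagation oracle (independent code path in the tests and the
acceptance script) agrees to ~1e-15 on random networks; row sums are exact
to machine precision, and global mass balance `Σ_i use_i·S[i,o] = P_o`
holds on balanced tables.

Processed commodities map one level onto primaries (flour → wheat at the
extraction rate); deeper commodity trees are out of scope. Real-data
pathologies (exports exceeding supply) would be scaled down with a logged
warning; synthetic tables cannot trigger this.

## 5. Livestock attribution

Feed is valued at *consumption-basis* impacts in the country producing the
animal product: the feed a country uses carries that country's provenance
portfolio for the feed crop, which is how soy grown in one region surfaces
in the footprint of meat produced in another. Grazing requirements
(km²·yr/kg) are an exogenous table — global grazing-yield data do not
exist at commodity level — supplied by the generator in a self-consistent
way. No multi-product allocation (milk vs meat from one herd) is
attempted; each product carries its own requirement row.

## 6. Footprints, exclusions, marginality

Footprints use FAO-style food supply as-is: post-production waste is
embedded in the consumption data and farm losses in production data, so no
separate waste correction is applied. Sugar is excluded from consumption
analyses by default because supply chains do not distinguish beet from cane
sugar; the exclusion is a flag, and production-side sugar statistics are
unaffected. Palm oil simply does not exist in synthetic worlds.

The import/domestic split is impact-weighted (share of ΔE, not of mass),
using the retained origin decomposition of each consumption impact.

Implied land per kg is `harvested_area/production` for crops and
`grazing + Σ feed_req × feed land` for animal products; baskets implying
more than 1,000 km² of land raise a marginality warning, since the
extinction layer is a marginal metric whose linear use degrades beyond
that scale. Per-capita baskets sit orders of magnitude below it; national
aggregates exceed it by design.

## 7. Diet engine

Scenario bookkeeping: held-constant commodities (stimulants/spices, which
carry negligible calories) keep their baseline intake, and their calories
are subtracted from the allocatable budget *before* group fractions are
applied — this makes every scenario's total calories equal the baseline's
exactly rather than to first order. Within a group, commodities keep their
baseline energy shares; kg intakes are kcal divided by energy density.
A positive group fraction with no baseline consumption in the group is an
error (there is no defensible way to invent a within-group mix). Sugar
receives calories but contributes zero impact. Scenario sourcing is the
country's current provenance: a scenario changes what is eaten, not where
it comes from, so scenario impacts are country-specific.

The shipped group-fraction table (fruit & veg / legumes & nuts / grains &
roots / dairy & eggs / ruminant meat / poultry & pig / sugar & other):
baseline 6/12/35/13/4/10/20%, planetary-health 12/23/43/8/1/5/8%,
vegetarian 40/10/35/15/0/0/0%, plant-based 40/25/35/0/0/0/0%; default
total energy 3,911 kcal/day.

The pipeline skips a reference scenario (with a logged warning) when the
chosen country's baseline has no consumption in a group the scenario
requires — strictness stays in the library, robustness in the driver.

## 8. Numerical conventions

* Production tonnes are converted to kg (×1000) at the per-cell impact
  stage; all impacts are ΔE per kg.
* Exact identities in the tests (no-trade equality, ×2 scaling laws) rely
  on IEEE arithmetic: scaling by powers of two is exact, and the type-1
  quantile returns an observed value, so scaled inputs yield exactly
  scaled outputs. Scaling by non-powers-of-two is verified to 1e-12.
* Nodata is −9999 in rasters; nodata cells never enter medians or sums.
* `ImpactValue.components` (crop/grazing/feed) always sum to the value;
  consumption-basis values retain their origin shares and origin values so
  downstream decompositions need no recomputation.
* Degenerate inputs fail loudly: zero/negative weights, q outside [0,1],
  production without harvested area, A > A0, singular provenance systems,
  missing table entries (named in the error), group fractions not summing
  to 1.

## 9. Problem sizes

Default tests run on worlds between 1×1 (closed-form checks) and 16×16
cells; the determinism check and the acceptance script use a 100×100-cell,
12-country, 10-commodity, 200-species world, 10,000 weighted-quantile
oracle cases and 1,000 random trade networks of up to 20 countries — sizes
at which every quantity stabilises while the whole suite runs in seconds.

## 10. Known limitations

Beyond the generator gaps in Section 2: single-level commodity trees; no
herd demography or milk/meat co-product allocation; no land-use intensity
classes (habitat is suitable or not); no price or substitution feedbacks
(explicitly a marginal analysis); aquatic foods out of scope (the metric is
terrestrial); no sub-national reporting units; and no uncertainty
propagation — per-pixel uncertainty in the extinction layer is upstream of
this package.
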