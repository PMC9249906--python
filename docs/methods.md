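# Methods

## Problem and scope

`biopump` explores whether systematically cultivating selected plant
species on marginal land would, over a multi-decadal horizon, sequester
more soil organic carbon (SOC) than is lost to water erosion. The workflow
is spatially explicit and consolidates marginal land into target areas
keyed by geopolitical world region × FAO Global Ecological Zone (GEZ),
then tests every candidate species against every target area for
pedoclimatic compatibility, and simulates SOC dynamics for the compatible
pairs from 2020 to 2100.

The package implements the framework at the level of gridded inputs and
consolidated units; it does not attempt to reproduce any particular global
map product, and it deliberately excludes socio-economic marginality
criteria, invasive-species risk, wind erosion, future-climate trajectories
and carbon-saturating soil models.

## Marginal-land identification

Five filters produce the marginal mask:

1. **Candidate covers** — bare land and sparsely vegetated areas (< 15 %
   vegetation) from a categorical land-cover raster. The class→role legend
   is configuration (an editable CSV shipping with an ESA-CCI-style
   22-class default), not code constants.
2. **Cropland abandonment** — cells that were cropland in an earlier
   epoch and transitioned to mosaic cropland/natural vegetation,
   grassland, sparse vegetation, bare areas, mosaic herbaceous cover or
   shrubland in the later epoch.
3. **SOC deficiency** — topsoil (30 cm) stock in (0, 50] Mg C ha⁻¹,
   binned into five 10-Mg classes with the upper bound inclusive
   (class = ⌈SOC/10⌉). Zero-SOC cells are treated as no-soil; negative
   values are reported and dropped.
4. **Protected-area exclusion.**
5. **Problem-land exclusion** — cells whose coded soil/terrain constraint
   is (sub-)severe. Severity codes are configuration; the default table
   covers the classic agricultural problem-land typologies (too cold, too
   dry, slopes > 30 %, shallow, poorly drained, saline/sodic, acid
   sulphate, peat).

Steps 3–5 are pure intersections, hence order-independent. Provenance
precedence is abandoned > sparse > bare, so a bare cell that also passed
the abandonment test is reported as abandoned; every retained cell carries
exactly one provenance code.

## Consolidation

Retained cells are labelled with region and GEZ ids from pre-rasterized
zone layers (water and polar GEZ codes excluded by default) and collapsed
into one `TargetArea` per occupied pair. Continuous attributes are
area-weighted means over the member cells, soil texture is the
area-weighted mode with ties broken toward the smallest code, and the
area is the sum of per-cell areas. Cell areas on geographic grids use a
cosine-of-latitude approximation of the geodesic cell size; an equal-area
projected CRS is honoured as-is. Monthly climate normals (temperature,
precipitation, potential evapotranspiration) are stored as 12-value
vectors per target area because the turnover model steps monthly. A zone
whose cells are entirely missing some attribute keeps its record but is
flagged unusable; matching then returns an explicit "unevaluable" result
rather than a silent non-match.

## Species records and carbon inputs

Each species carries absolute tolerance ranges (mean annual temperature,
annual precipitation, pH, texture classes, altitude, compatible GEZ set),
life form (grass/crop/tree), lifecycle (annual/perennial with a rotation
lifetime), dry-matter fractions with carbon contents and field-return
shares, a deciduous flag, a RUSLE cover-management factor and the months
with soil cover. Absolute (rather than optimal) tolerance ranges drive the
matching to maximize candidate coverage; a stricter screen can be obtained
by editing the trait table. A Köppen→GEZ harmonization table (editable
CSV, many-to-many, default shipped with the package) converts
climate-zone descriptors from crop databases into GEZ sets.

Annual carbon input to the soil follows a fractioning-and-partitioning
scheme over product, stem, leaf and root compartments:
`dm_f × c_f × return_f` per fraction. Perennials are annualized over the
rotation assuming an uneven-aged stand: product/stem and evergreen-leaf
returns are spread linearly over the lifetime, deciduous leaves return
every year, and root carbon — resident for the whole rotation — is
divided by the lifetime. An optional root multiplier (default 1.0, i.e.
off) can fold rhizodeposition into the root compartment.

## Matching

A pair matches when all six criteria hold: mean annual temperature,
annual precipitation sum, pH, modal texture membership, elevation, and
GEZ membership. Matching is binary; no suitability scoring. The default
temperature screen uses the annual mean of the 12 normals; a
`monthly_extremes` option additionally requires every month inside the
range. The altitude lower bound defaults to −500 m when a record omits
it.

## SOC turnover model

The five-pool monthly turnover model follows RothC v26.3 semantics:
decomposable plant material (DPM, k = 10 yr⁻¹), resistant plant material
(RPM, 0.3), microbial biomass (BIO, 0.66), humified organic matter (HUM,
0.02) and inert organic matter (IOM, no decay). Monthly decay of each
active pool is `exp(−a·b·c·k/12)` with

- `a(T) = 47.91 / (1 + exp(106.06/(T + 18.27)))`, zero at and below
  −18.27 °C;
- `b` from the accumulated topsoil moisture deficit: the deficit
  integrates monthly P − PET, clamped to [maxTSMD, 0] with
  `maxTSMD = −(20 + 1.3·clay − 0.01·clay²)·depth/23`, divided by 1.8 for
  bare soil; `b = 1` down to 0.444 of the maximum deficit, then declining
  linearly to 0.2;
- `c = 0.6` for vegetated months, 1.0 for bare months.

Decomposed carbon splits into CO₂ : BIO : HUM as `x : 0.46 : 0.54` with
`x = 1.67·(1.85 + 1.60·exp(−0.0786·clay))`. Plant input splits DPM:RPM by
a vegetation-class ratio — 1.44 for crops and grassland-type vegetation,
0.25 for woodland — overridable per species. Input enters after the decay
step of its month, so the exact mass balance ΔSOC = inputs − respiration
holds to machine precision over any run.

Pools are initialized from the measured stock by pedotransfer
regressions: `IOM = 0.049·SOC^1.139` (Falloon), `RPM = (0.1847·SOC +
0.1555)·(clay + 1.2750)^−0.1158`, `HUM = (0.7148·SOC +
0.5069)·(clay + 0.3421)^0.0184`, `BIO = (0.0140·SOC +
0.0075)·(clay + 8.8473)^0.0567`, DPM as the remainder. When the
regressions overshoot the stock (common around 30 Mg C ha⁻¹), DPM is
floored at zero and RPM/HUM/BIO are rescaled proportionally so the pools
sum to the stock exactly. All constants live in `RothCParams` and can be
replaced wholesale.

Climate is a recycled 12-month normal — the simulation deliberately
ignores transient climate change. PET inputs are used directly; a 0.75
open-pan correction is available behind a flag for open-pan
evaporation series. The horizon 2020–2100 is treated as 80 years, which
is also the annualization divisor.

## Erosion coupling

The mapped soil-loss rate (RUSLE-based, Mg soil ha⁻¹ yr⁻¹) is rescaled by
the ratio of the species' cover-management factor to the map's reference
factor (default 0.5, representative of bare/sparse cover), exploiting the
linearity of RUSLE in the C factor. The annual carbon loss multiplies the
adjusted rate by the topsoil carbon concentration — the year's simulated
stock over a fixed topsoil mass (bulk density × depth), with an
enrichment ratio defaulting to 1.0. Coupling is offline by default: the
losses never feed back into the pools, and the reported net stock is
final SOC (prior to erosion) minus cumulative eroded SOC, mirroring how
the two quantities are bookkept separately in large-scale assessments. An
online mode that removes each year's loss proportionally from all pools
is available for sensitivity analysis.

## Best cases and statistics

A pair is net-positive when net SOC > 0 at the horizon end — either
genuine accumulation or a drawdown of the initial stock that stops short
of zero; the latter is flagged (`initial_loss_flag`) when the positive net
still sits below the initial stock. Per target area the net-positive pair
with the highest net stock is the best case; exact ties break toward the
lexicographically first taxon for determinism. Initial-vs-final stocks
over the best cases are compared with a two-sided paired t-test
(zero-variance differences yield an explicit degenerate result, no
p-value). Reported integer percentages round half-up; rates use two
decimals; every share is stored alongside its numerator and denominator.

## Synthetic world

The generator builds a toy geographic grid (default 100×100 cells of
0.01°, near the equator) with regions as vertical bands and GEZ as
horizontal bands, plants known numbers of bare/sparse/abandoned cells and
removes known subsets through each filter, so all identification counts
are pure set arithmetic. Every pedoclimatic attribute is constant within
its band, making zonal aggregates exact and letting the generator derive
the expected match matrix with its own independent comparison loops.
Default pedoclimatic bands span tropical (mean 26 °C) to boreal (2 °C)
conditions with sinusoidal monthly normals (noise optional, off by
default so annual means are exact).

Erosion outcomes are decided by construction: benign zones carry
soil-loss rates of ~1 Mg ha⁻¹ yr⁻¹, low enough that every matched pair
stays net-positive, while one designated stress zone carries an extreme
rate chosen so that cumulative erosion must exceed any attainable final
stock (the inert pool bounds the eroded series from below and mass
balance bounds the final stock from above). The stress rate is a
correctness device for exact ground-truth counting, not a calibration of
real erosion. Consequently the fixture does not emulate: realistic
geography or spatial autocorrelation, intermediate erosion regimes where
the net sign is genuinely marginal, climate trends, or missing-data
patterns beyond the configurable zone-drop cells. Passing the end-to-end
suite therefore demonstrates correct plumbing and arithmetic, not
predictive skill on real landscapes.

The default species panel contains five engineered records — a universal
matcher, an acid-soil crop, a tropical tree, a high-altitude steppe grass
and a deliberate non-matcher — with annual carbon inputs between 1.5 and
3 Mg C ha⁻¹ yr⁻¹ and cover factors between 0.2 and 0.6, inside the
bounds the erosion construction assumes.

## Numerical choices and edge cases

- Rasters: ESRI ASCII grid (text, bit-exact integer round-trips) and
  GeoTIFF via `tifffile`; zones are consumed pre-rasterized; cross-CRS
  resampling is out of scope — `align_to_grid` requires matching CRS and
  offers nearest-neighbour (categorical) and separable area-weighted mean
  (continuous) resampling only.
- Zonal mode ties break toward the smallest category code; empty zones
  are absent from aggregate tables, never reported as zero.
- The moisture modifier treats `|deficit| = 0.444·|max|` as full activity
  (the linear branch is continuous there anyway).
- Degenerate pedotransfer inputs (IOM ≥ stock) clamp IOM to the stock and
  zero the active pools.
- The 80-year pair simulation is a plain Python monthly loop (960 steps,
  ~3 ms); the end-to-end default world (16 areas × 5 species) runs in
  well under a minute.

## Known limitations

- The pedotransfer constants are a published general-purpose set; site
  -calibrated constants can be supplied through `RothCParams` but no
  fitting utilities are provided.
- Precipitation tolerance is compared against the annual total, not
  growing-season totals.
- Erosion uses a single enrichment ratio and ignores deposition/burial;
  eroded carbon is treated as removed from the unit, with no statement
  about its atmospheric fate.
- The turnover model is non-saturating: very high inputs produce
  unbounded equilibrium stocks.
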