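# Methods

This note documents the models and conventions `nppdb` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model

The database is a twelve-table set (CSV directory or SQLite file): site
information, NPP estimates, three methodology catalogues (aboveground,
belowground, whole-plant), monthly climate normals, and six pass-through
ancillary tables.  All production values are g dry mass m⁻² yr⁻¹; rows
reported in g C are converted at load time by dividing by the stored
carbon-content fraction.  A g C row without a carbon content is a validation
error — no default fraction is imputed, because that would fabricate data.
Validation is total: every input row is either accepted into the typed
containers or lands in a structured issue report naming its table, row and
field; nothing is dropped silently.  Deposits with different headers are
adapted through a YAML column/table-name mapping rather than by editing the
reader.

Components form a closed vocabulary (stem, branch, foliage litter, extra
litter, reproductive, herb, shrub, non-vascular, understory, fine root,
coarse root, herbivory, tropical leaf decomposition, VOC/exudates/symbionts,
total NPP), with the verbatim source label preserved in `original_label`.
Every record's method must have a scope compatible with its component — a
belowground method can never tag a foliage record.

## Summation hierarchy

Eight gated levels: herb+shrub ANPP; non-tree ANPP (+ non-vascular); wood
ANPP (stem + branch); total litterfall ANPP (leaf + extra litter); tree
ANPP (wood + litterfall); BNPP (fine + coarse roots); total NPP 1
(tree + non-tree + BNPP); total NPP 2 (total 1 + herbivory + reproductive
material when not already inside litterfall + rapidly decomposed leaf litter
in tropical forests).  A level is *complete* only when every constituent is
measured or verified absent; it is *not applicable* when everything in it is
absent (it then contributes zero upward); otherwise it is *incomplete* and
no value is emitted.  Gating is monotone: new measurements or absence flags
can only complete levels, never un-complete them.

Conventions pinned here:

- Outside forests, all root production is assumed captured by the fine-root
  estimate, so coarse roots are treated as covered when not measured.
- The tree/overstory branch is treated as structurally absent in grassland,
  cropland, tundra and peatland unless tree components were actually
  measured; shrub woody increments in tundra/peatland ride in the shrub slot.
  Forests and woodland-savanna/dry shrubland keep the full hierarchy.
- Whether "extra litter" includes reproductive material is source-dependent;
  a per-record flag records it, and a separately measured reproductive value
  alongside that flag raises a double-count error.
- The understory expectation in forests is met either by an explicit
  understory record or by the herb and shrub layers both being covered.
- Sites whose components come from different campaigns (years/methods) are
  still summable on the site-mean view but carry a `mixed_campaign` stamp.

The main/minor component expectations are tabulated per ecosystem type
(boreal forest, tropical forest, other forest, fruit plantation, grassland,
cropland, peatland/tundra with and without substantial non-vascular
vegetation, woodland savanna).  A site missing a *main* component fails the
completeness audit and would not qualify for a harmonized compilation;
missing *minor* components are informational.  Coarse roots are minor in all
woody types because they are nearly always derived from aboveground
components rather than measured.

## Uncertainty model

Per measurement: `S = P · RF / √l`.  The spread `P` is half the 90th–10th
interpercentile range of site-level values per (biome, component class),
computed from the database itself with linear-interpolation percentiles (the
common spreadsheet/statistics default; configurable, and an externally
supplied P table can replace the recomputation for exact replication
against a published spread table).  Biome–class cells with fewer than two
sites fall back to the all-biome pooled spread with a logged warning, so
small subsets stay processable.

The RF catalogue is fixed: aboveground {0.1, 0.2, 0.3, 0.4, 0.4, 0.4, 0.8},
belowground {0.2, 0.3, 0.3, 0.6, 0.6, 0.7, 0.8, 0.9}, whole-plant
{0.6, 0.6, 0.6, 1.0}.  When several methods measured one main part, the
combined RF is the arithmetic mean rounded to one decimal; exact .x5
midpoints round toward the RF of the dominant component — fine roots for
belowground production, otherwise the largest flux — and toward the more
accurate method when dominance is unknown.  The arithmetic runs in integer
tenths, so no floating-point midpoint ambiguity exists.

Whole-database orchestration groups records into measurement campaigns by
(component class, measurement years).  Each campaign gets one combined RF
and the *shortest* series length among its records (the conservative
choice).  Campaigns aggregate per site as `√(Σ S²)/N`; the above- and
belowground site values combine in quadrature to the total; whole-plant
measurements (radiocarbon, peat accumulation, process models, eddy-flux
budgets) contribute to the total directly, bypassing quadrature, and when
both routes exist they are pooled by the same `√(Σ S²)/N` rule.  Error
propagation stops at the ANPP/BNPP split: a finer per-component propagation
would require splitting the method reduction factors per component, which
the catalogue deliberately does not do.

## Classification

*Biome* (six classes) from production shares and site attributes, with the
fixed precedence: annual crops → cropland; above the treeline → tundra;
woody share > 50 % outside arid climate → forest (woody-dominated arid sites
with reduced patchy cover → dry shrubland); herb share > 50 % → grassland;
shrub/herb co-dominance (< 50 % each) in cold climate → peatland; dry with
reduced patchy cover → dry shrubland.  Transition zones resolve by the
larger share.  Unclassifiable attribute combinations return the reasons
rather than guessing.  The classifier doubles as a validator against stored
labels, which encode expert judgment the rules only approximate.

*Management* (managed/unmanaged): croplands always managed; forests managed
iff thinned/harvested ≤ 50 yr, fertilized ≤ 25 yr, or a plantation < 10 yr
old (older untouched plantations count as natural); grasslands managed iff
fertilized, irrigated, intensively grazed or established the measurement
year — annual burning, low-moderate grazing and non-intensive mowing leave
them unmanaged; tundra/peatland/dry shrubland managed only when fertilized
in a manipulation experiment.  Missing antecedents default to unmanaged with
a low-confidence flag.

*Köppen-Geiger main class* from monthly normals, in order: polar if the
warmest month < 10 °C; arid if annual precipitation < 10 × the dryness
threshold (2·MAT, 2·MAT + 28 or 2·MAT + 14 for winter-concentrated,
summer-concentrated or evenly distributed precipitation, with 70 % of the
annual total in a half-year as the concentration cut, inclusive); tropical
if the coldest month ≥ 18 °C; temperate if the coldest month > 0 °C; cold
otherwise.  The 0 °C temperate/cold boundary follows the modern 1-km map
formulation (the classic −3 °C variant is an argument).  Summer is Apr–Sep
in the northern hemisphere and Oct–Mar in the southern; equatorial sites
use the northern convention.

*Aridity*: AI = annual precipitation / annual PET, undefined at PET = 0.
The published class intervals are open, leaving boundaries unassigned; here
each lower boundary joins the wetter class — hyper-arid [0, 0.03), arid
[0.03, 0.2), semi-arid [0.2, 0.5), dry sub-humid [0.5, 0.65], humid
(> 0.65, strict, so AI = 0.65 stays dry sub-humid).  The five classes
partition [0, ∞).

## Quality control

Three advisory checks (QC never mutates data): coordinate bounds, with
off-land detection only when a user-supplied gridded land mask is given;
recomputed-vs-stored summation levels with a 1 g m⁻² yr⁻¹ default tolerance
to absorb source-table rounding; and biome- or climate-stratified boxplot
outliers with the standard k = 1.5 whisker rule (configurable — the whisker
convention is not a law of nature), skipping strata with fewer than five
sites.  Quartiles use the same percentile convention as the spread table.

## Weighted regression

Miami model: `NPP = min(A/(1+exp(b − c·T)), A·(1 − exp(−d·P)))`, classic
coefficients A = 3000 g m⁻² yr⁻¹, b = 1.315, c = 0.119 °C⁻¹,
d = 0.000664 mm⁻¹ as defaults and initial values.  Fits minimise
`Σ wᵢ (NPPᵢ − NPP(Tᵢ, Pᵢ))²` with `wᵢ = 1/Sᵢ²` (normalised by the mean
weight, which leaves the argmin untouched and makes the all-equal-S case
coincide exactly with the unweighted objective) or `wᵢ = 1`.  Sites with
S = 0 are floored at the smallest positive S.  Because the min() kink makes
the objective non-smooth, optimisation is derivative-free (adaptive
Nelder-Mead on (log A, b, c, log d), keeping A and d positive) with 8
seeded multi-starts, an f-tolerance tied to the objective's magnitude, and
the best converged solution kept.  `compare_fits` reports the relative
reduction in mean predicted NPP from weighting over any evaluation set;
positive values mean weighting lowered the surface.

## Synthetic data generator

The generator emulates the *structure* the pipeline assumes, at the
marginals of the real compilation: 456 sites by default with biome
proportions 206/145/34/34/21/16 (forest/grassland/cropland/peatland/tundra/
dry shrubland) and climate-region proportions 191/125/80/45/14
(cold/temperate/tropical/arid/polar, normalised by their 455 total); series
lengths 42 % single-year, 50 % in 2–5 yr, 8 % in 6–16 yr; 50/456 of sites
carrying only a whole-plant estimate; and a configurable fraction (default
5 %) of sites with a deliberately dropped main component for gating tests.
Climate regions are drawn compatibly with the biome (no tropical tundra),
monthly normals come from per-region templates with jitter chosen so they
re-classify to the intended Köppen class ≥ 95 % of the time, true site NPP
follows the Miami surface over the site's MAT/MAP, component values split
the truth by biome-specific fractions, methods are sampled per component
from the catalogue with matching scope, and observed values add Gaussian
noise with spread ∝ RF/√l times a biome-scale proxy for P — so harmonized S
genuinely tracks data quality.  One global seed drives named sub-streams
per table, so extending one table never perturbs another.

What it does *not* emulate: real geography (coordinates are uniform within
latitude bands), spatial or temporal autocorrelation, correlated method
choices within studies, reporting biases, or the long right tail of real
within-biome NPP distributions.  Passing tests on synthetic data therefore
demonstrate the correctness of the pipeline's logic and algebra under known
truth, not the ecological realism of any fitted surface.  Note that clean
(even noise-free) synthetic data still yields boxplot outliers within
biomes, exactly as genuine extreme-climate sites do in real compilations —
outlier flags are review prompts, not errors.

## Numerical choices

- Percentiles: linear interpolation between order statistics everywhere,
  configurable where it matters (spread table, QC quartiles).
- RF rounding: exact integer-tenths arithmetic; midpoint policy above.
- Fit termination: Nelder-Mead xatol 1e-9 with fatol scaled to the initial
  objective; multi-start count and seed are arguments.
- CSV round-tripping: floats written as %.17g and parsed with round-trip
  precision, so write→read is value-identical.
- Test and example problem sizes (60–456 synthetic sites, 50 Monte-Carlo
  replicates for the weighted-fit comparison) are chosen to exercise every
  code path at desk scale while keeping the full suite fast.

## Known limitations

- The biome classifier needs production shares or explicit attributes; it
  does not infer them from the NPP records.
- Whole-plant and split-component uncertainty routes are pooled by the
  site-aggregation rule when both exist at one site; other conventions are
  defensible.
- The land mask is nearest-cell lookup on a regular grid; no coastline
  geometry.
- Excel input is out of scope (CSV and SQLite are canonical); no gap-filling
  of missing minor components is attempted.
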