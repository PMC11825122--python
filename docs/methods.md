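# Methods

## Demand model

`oxyquant` treats national oxygen demand as a static annual expectation.
For ward *w* of facility *f* with category *t*:

* per-patient volume `V_w = flow_w [L/min] × 60 × duration_w [h]` — the
  gaseous-oxygen volume one typical hypoxaemic case consumes over a full
  course of therapy;
* expected caseload `N_{f,w} = prevalence_w × beds_{f,w} × turnover_t ×
  occupancy` — the expected number of hypoxaemic patients admitted per year;
* ward demand `D_{f,w} = V_w × N_{f,w}`, summed over wards to the facility
  and over facilities to category, regional, and national totals.

Assumptions worth making explicit:

* **Turnover is a facility-category property.** Bed turnover rates are
  available per hospital category only, so every ward of a facility uses its
  category's rate. A ward-specific refinement would be a data change, not a
  code change.
* **Occupancy defaults to 1.** The caseload formula in common planning
  practice omits occupancy; it is exposed as an optional multiplicative
  factor in `[0, 1]` so analyses that model partial occupancy can include it
  without changing the default arithmetic.
* **Caseloads are fractional.** They are expectations; rounding to whole
  patients would bias small wards and break the exactness of the worked
  examples.
* **Monthly = annual / 12.** Turnover rates are annual; a uniform division
  is the only conversion consistent with them. No seasonality or epidemic
  surge is modelled.
* **Linearity.** Demand is linear in each of beds, turnover, prevalence,
  flow, and duration separately, and any zero factor zeroes the ward's
  demand. The test suite asserts both properties.

### Parameters and defaults

Ward assumptions (prevalence stored as a fraction; duration in hours; CSV
inputs may give days, converted ×24 via an explicit `duration_unit` column):

| ward | prevalence | flow (L/min) | duration (h) |
|---|---|---|---|
| outpatient | 0.00 | 5 | 1 |
| adult_medicine | 0.06 | 6 | 144 |
| paediatrics | 0.10 | 2 | 72 |
| neonatology | 0.20 | 2 | 72 |
| intensive_care | 1.00 | 6 | 96 |
| operating_theatre | 1.00 | 8 | 6 |
| emergency | 0.40 | 6 | 16 |
| maternity | 0.13 | 5 | 12 |
| recovery | 1.00 | 5 | 6 |

Facility categories (count / beds / annual bed turnover): general 4/919/41,
central 13/2595/96, regional 15/2487/72, district 67/5090/58. The
unweighted mean turnover across the four categories is 66.75; a bed-weighted
variant (`bed_weighted_turnover`, ≈ 68.6) is exposed separately because the
two answer different questions — the category-level average versus the rate
an average bed experiences. The shipped bed counts sum to 11 091; the
assessment this registry mirrors also circulated a grand total of 11 111
that does not equal its own row sum, and the package deliberately stores
rows as given and always computes totals rather than adopting either printed
grand total.

Both vocabularies are open registries: the worked examples themselves use a
COVID treatment ward absent from the nine defaults, and a neonatal entry
with a 1 L/min flow where the default table carries 2 L/min — the engine
takes whatever assumption registry it is given rather than guessing which is
intended. Regions default to ten anonymous labels `R01`–`R10`; the
arithmetic never depends on the names.

## Gap analysis

Coverage is `available_functional / required` with two degenerate cases:
no requirement and no stock is vacuous full coverage (1); stock without a
computed requirement reports an infinite surplus sentinel rather than a
misleading ratio. Absolute gaps are clamped at zero **within the scope at
which they are computed**: a surplus region never offsets another region's
deficit unless gaps are recomputed at the national scope. Clamped gaps are
therefore deliberately not additive — the sum of regional clamped gaps is ≥
the national clamped gap, and the test suite pins this inequality.

Device requirements for concentrators, oximeters, and monitors are planning
inputs (norms per facility type or region), never derived from litres.
Cylinders are the exception: their requirement is natively volumetric, so a
demand volume is compared against functional-cylinder capacity
(`functional × cylinder_size`, default 7 500 L per cylinder). Volumes
convert to cylinder equivalents in three modes: `exact` (divide),
`procurement` (ceiling — fractional cylinders cannot be bought), and
`reporting` (3 significant figures, the headline-number convention: 140
million litres reads as 18 700 cylinders of 7 500 L).

## Indicators

The monthly facility report carries a litre-denominated stock ledger
(opening, received, consumed, lost, closing), device functionality splits,
staffing, and patient outcomes. The ledger identity
`opening + received − consumed − lost = closing` is validated to ±1 L
absolute — generous enough for records rounded to whole litres, tight enough
to catch any real bookkeeping error; violations are reported with their
residual, never silently repaired.

Indicator definitions live in a machine-readable catalogue
(`oxyquant.indicators.CATALOGUE`: id, name, unit, numerator, denominator,
aggregation rule) so they are auditable and overridable. Conventions:

* ratio indicators pool numerators and denominators across facilities before
  dividing — never a mean of facility or regional percentages — which keeps
  small-denominator facilities from dominating (a pinned test shows pooling
  and mean-of-regions disagree on unequal region sizes);
* pulse-oximeter functionality is device-level (Σ functional / Σ total);
  respirator and oxygen-generator functionality is facility-level (share of
  facilities with ≥ 1 functional unit), optionally stratified by a
  configurable facility-category mapping, since category definitions vary by
  country;
* undefined ratios (zero pooled denominator) are emitted as missing values
  with a reason string, not as zeros;
* quarterly stock-out burden is the mean over facilities of the summed
  stock-out days across the quarter's three months; facilities missing a
  month are excluded by default (`missing_month="zero"` counts absent months
  as zero), and the policy used is recorded in the value's status field;
* the cylinder census counts all 7 500 L cylinders, full or empty.

The duplicated oximeter row in common indicator listings is treated as a
single indicator, giving 13 distinct catalogue entries.

## Synthetic data

No facility-level dataset from the national assessment that motivates the
default registries is published, so the generator emulates its structure:
99 facilities (4 general, 13 central, 15 regional, 67 district) holding the
category bed totals exactly, allocated over 10 regions by configurable
weights. Beds are split evenly over a category's facilities and over wards
by share fractions, both via largest-remainder rounding, so category bed
totals are conserved to the bed. The default ward shares (general medicine
0.22, maternity 0.18, paediatrics 0.16, theatre 0.12, emergency 0.10,
recovery 0.07, neonatology 0.06, outpatient 0.05, intensive care 0.04) are a
plausible hospital mix chosen once for realism; they are a config entry, not
a claim about any real facility network.

Monthly reports are generated so that every downstream estimator has a known
truth: hypoxaemic caseloads are Poisson with mean equal to the facility's
monthly expected caseload from the demand engine (tying the report stream to
the quantification model); patients given oxygen are Binomial(caseload,
coverage = 0.7); successes Binomial(given, 0.75); stock-out days
min(Poisson(1.5/month), days in month); the hypoxaemia-department flag is
Bernoulli(0.6) per facility; staff training Binomial(20, 0.65). Stock flows
are uniform draws at a 50 000 L/month scale with closing derived from the
identity, so the ledger balances exactly by construction. Equipment totals
are Poisson per bed (concentrators 0.10, oximeters 0.15, monitors 0.08,
cylinders 0.02 — cylinders deliberately scarce) with functional counts
Binomial(total, 0.8). A fixed seed reproduces the entire pipeline
byte-for-byte; the roster, inventory, and report streams use independent
child seeds so adding months never perturbs the roster.

What passing tests on this data do and do not show: they verify the
arithmetic, aggregation, and estimator conventions end-to-end and that
generator parameters are recovered within sampling tolerance (3 standard
errors at ≥ 500 facility-months). They do not validate the clinical
assumption values against any real population, nor reproduce the real
assessment's regional distributions, which were never published as numbers.
The synthetic national monthly demand (~190–200 M litres with default
shares) lands in the same order of magnitude as real national estimates for
a comparable facility network, which is a realism check, not a calibration.

## Numerical choices

* All litre quantities are double precision; CSVs serialize at full
  precision (`%.17g`, round-trip float parsing) and only human-readable
  summaries round to 3 significant figures.
* `round_sig` rounds half away from zero, matching how headline planning
  figures are conventionally reported.
* Largest-remainder apportionment breaks remainder ties by slot order,
  making allocation deterministic.
* Roll-ups are plain sums; conservation across partitions holds to ~1e-15
  relative and the brute-force oracle comparison is asserted at 1e-6.

## Limitations

* The model is a static annual expectation: no seasonality, epidemic surge,
  or within-year stock dynamics.
* Turnover and occupancy are category-level; ward-level admission data would
  supersede both.
* Equipment requirement norms are inputs; the package does not reconstruct
  the planning norms behind published coverage percentages.
* The indicator catalogue fixes one reasonable formula per indicator name;
  jurisdictions with different conventions should override the catalogue.
* No DHIS-2 connectivity: the indicator stage consumes flat CSV exports
  only, and no procurement, distribution-logistics, or plant-sizing
  modelling is included.
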