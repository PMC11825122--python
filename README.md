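# oxyquant

Medical-oxygen needs quantification for national health-system planning.

Health ministries in resource-limited settings must size oxygen production,
storage, and equipment investments against the demand created by hypoxaemia —
abnormally low blood oxygen — across their facility network, usually without
patient-level admission data. `oxyquant` implements the standard
facility-assessment approach to this problem: ward-level clinical assumptions
combined with facility bed counts and turnover rates yield an expected annual
oxygen volume, which is rolled up to facility, category, regional, and
national totals, compared against equipment stocks, and monitored through a
DHIS-2-style indicator set computed from monthly facility reports. It is
aimed at analysts supporting oxygen system planning and at anyone who needs a
tested, scriptable alternative to spreadsheet-based oxygen quantification
tools.

## The model

For one ward of a facility, the expected annual oxygen need in litres is

```
V_patient = flow_rate [L/min] × 60 × duration [h]          (one typical case)
N_patients = prevalence × beds × turnover × occupancy      (expected cases/yr)
D_ward     = V_patient × N_patients
```

where `prevalence` is the hypoxaemia prevalence among the ward's admissions,
`turnover` the annual bed turnover rate (patients per bed per year, a
facility-category property), and `occupancy` an optional average bed
occupancy factor (default 1). Facility demand is the sum over its wards;
category, regional, and national demand are sums over facilities; monthly
demand is annual / 12. Expected caseloads are kept fractional — they are
expectations, not counts.

The package ships default parameter registries: clinical assumptions for nine
standard hospital wards (outpatient, adult medicine, paediatrics,
neonatology, intensive care, operating theatre, emergency, maternity,
recovery) and bed/turnover parameters for four hospital categories (general,
central, regional, district — 99 facilities in total, unweighted mean
turnover 66.75). Both vocabularies are open: user wards such as a COVID
treatment ward are added through the same CSV inputs.

Around the demand core sit three more stages:

* **gap analysis** — coverage (`available / required`) and zero-clamped
  absolute gaps per device class at a declared scope, plus volumetric
  cylinder gaps and conversion of volumes to cylinder equivalents
  (exact, procurement ceiling, or 3-significant-figure reporting precision);
* **indicators** — a machine-readable catalogue of 13 hypoxaemia-management
  and oxygen-use indicators (stock ledger totals, stock-out days, device
  functionality, therapy coverage, therapeutic success, staff training),
  pooled over numerators and denominators, with ledger validation
  (`opening + received − consumed − lost = closing`);
* **synthetic data** — a seeded generator producing facility rosters with
  exact category counts and conserved bed totals, equipment inventories, and
  monthly report panels whose parameters downstream estimators can recover.

## Worked example

A roster holding the two classic textbook wards — a 10-bed neonatal ward
(20% prevalence, 1 L/min for 3 days, turnover 50) and a 5-bed severe-COVID
adult ward (100% prevalence, 10 L/min for 7 days, turnover 25):

```
$ oxyquant demand --roster roster.csv --assumptions assumptions.csv \
      --type-params types.csv --out demand.csv
national annual demand: 13,000,000 L (1,090,000 L/month)

$ cat demand.csv
grouping,group_key,annual_litres,monthly_litres,expected_hypoxaemic_patients
facility,hf-neo,432000.0,36000.0,100.0
facility,hf-covid,12600000.0,1050000.0,125.0
...
national,national,13032000.0,1086000.0,225.0
```

The neonatal ward needs 4 320 L per patient × 100 expected hypoxaemic
patients per year = 432 000 L annually; the COVID ward 100 800 L × 125 =
12 600 000 L; together 13 032 000 L per year (shown to 3 significant figures
in the console summary, at full precision in the CSV). The same library
calls are available in Python:

```python
from oxyquant import per_patient_volume, caseload, ward_annual_need

vol = per_patient_volume(flow_rate=1, duration=72)     # 4320.0 L
load = caseload(prevalence=0.20, beds=10, turnover=50) # 100.0 patients/yr
ward_annual_need(vol, load).annual_litres              # 432000.0 L
```

The full synthetic pipeline — generation, demand, gaps, indicators — runs as

```
$ oxyquant all --seed 42 --out results/
oxyquant 0.1.0  seed=42  config=95504967cac0
facilities: 99   facility-months: 297
national annual demand:  2,360,000,000 L
national monthly demand: 197,000,000 L
cylinder volume gap (regional clamp): 2,360,000,000 L = 315,000 x 7,500 L cylinders
  pct_hypoxaemia_dept              57.6 %
  ...
```

and writes `roster.csv`, `inventory.csv`, `reports.csv`, `demand.csv`,
`gaps.csv`, `indicators.csv`, and a human-readable `summary.txt`. Re-running
with the same seed and config reproduces every output byte-for-byte.

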