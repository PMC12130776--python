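# Methods

## Data model

The pipeline treats national pharmacy-claims open data as three
month-indexed inputs:

1. **Monthly report tables** per category: the top-100 medications ranked
   by prescribing frequency, the top-100 ranked by ingredient cost, and
   complete totals per therapeutic group. Each row carries entity name,
   ATC code, monthly dispensing frequency, % share of all scheme
   dispensings, ingredient cost (EUR) and % share of total cost. The two
   medication rankings for a month are merged into a single entity set;
   when both list an entity with conflicting numbers, the frequency-ranked
   row wins (frequency is the primary ordering) and a data-quality warning
   is logged. Product groups from the "Various" (V) physiological system
   that appear below ATC level 5 among the medications — urinary
   requisites, diagnostic agents, needles — are excluded from the
   medication data and analysed only as therapeutic groups, where their
   coverage is complete.
2. **Eligibility counts**: persons eligible for the scheme, published per
   geographic area; exactly one breakdown level is summed per month (the
   source publishes two overlapping ones, so summing both would double
   count).
3. **A monthly Consumer Price Index** for deflation.

Months are first-class `(year, month)` keys serialised as `YYYY-MM`;
day-level dates never enter the model. The published %-share columns are
carried through as printed and never re-derived or corrected, since their
denominator (all scheme dispensings) is not otherwise available.

## ATC hierarchy

Entities are keyed by WHO ATC code; the level (1–5) is derived from the
code's shape, and ancestry is prefix truncation. Analyses use levels 5
(medications), 2 (therapeutic groups) and 1 (physiological systems);
levels 3–4 are representable because the source publishes some
non-medication groups at level 3. Display names are metadata only — they
vary in spelling and case across monthly files, so they never participate
in identity.

## Metrics

Per entity and month: prescribing frequency *f*, ingredient cost *c*,
cost per prescribing *c/f* (undefined, hence missing, at *f* = 0),
prescribing rate *1000·f/E* and cost rate *1000·c/E* with *E* the
scheme-eligible persons that month. Cost-bearing metrics can be deflated
by *P_ref/P_t*; the reference month defaults to the latest month in the
CPI series, so costs are expressed at end-of-coverage prices. Frequency
metrics are never inflation-adjusted (requesting it is an error).

Derivation order is fixed so the five metrics stay mutually consistent:
disruption correction on the raw frequency and cost inputs first, then
ratio/rate derivation, then deflation. Deflation by the same month's CPI
commutes with the cost-per-prescribing ratio, which is covered by a
property test.

### Missing data

Absence from a top-100 list means the true value is unknown but at most
the 100th-ranked value. Such months are `missing`, never zero; missing
propagates through every derivation step, exports show empty cells and
plots show line gaps. No imputation of censored months is attempted.

### Disruption correction

A one-off transmission outage (May 2021 in the Irish data) depressed one
month's apparent dispensing and inflated the next. Where a series has
values in both configured months, both are replaced by the weighted mean
`(w_a·x_a + w_b·x_b)/(w_a + w_b)` and flagged `imputed`; where only one
month is observed, nothing changes — the observed value belongs to its own
month and is never copied to the other. The weights default to the number
of calendar days in each month (31, 30 for May/June) because dispensing
volume scales with days of trade; equal or custom weights are a parameter.
With equal weights the correction conserves the two-month sum exactly, and
the corrected value always lies between the two inputs.

## Hierarchy comparison

The proportion of a higher-level entity accounted for by a strict ATC
descendant is the month-wise ratio of their series, reported in [0, 1].
Parent values come from the therapeutic-group/physiological-system
reports, which are complete totals — never from summing censored
children. Because the per-1,000 rate denominators cancel month-wise,
rate ratios equal raw-value ratios; the implementation computes
proportions from whatever consistent pair it is given and tests the
equivalence as a property. A physiological-system (level 1) series is the
sum of that system's level-2 group rows, which is valid precisely because
group reports are untruncated. Exactly two entities (child, parent) are
compared per call.

## Seasonal profile

For calendar month *m*, the index is the mean of observed values falling
in *m* divided by the overall observed mean; missing points are excluded
from both. At least 12 observed points are required. The
observation-count-weighted mean of the indices is 1 by construction, so
an index of 1.35 in December reads directly as "35% above the typical
month".

## Synthetic generator

The generator emulates the portal's publication process, not patient-level
dispensing. Each entity's expected frequency is

```
baseline · trend^t · (1 + amplitude·cos(2π(month − peak)/12)) · ∏ steps
```

with expected cost = frequency × step-adjusted unit cost. Noise is
multiplicative lognormal with unit mean and coefficient of variation
`noise_cv` (counts and costs are positive and large, so relative noise is
the natural scale), drawn from one seeded stream per entity keyed by a
stable hash of the ATC code — adding an entity never perturbs the others.
Frequencies are rounded to integers after noise; with `noise_cv = 0` the
exact closed-form values are written instead, so noise-free bundles
reproduce the analytic truth to floating-point precision and serve as the
pipeline's exact oracle. Generated %-share columns use a configured tail
mass (dispensings outside the modelled entities, with its own unit cost)
as part of the denominator, so shares sum to under 100% as in real files
where the top 100 is a subset. The disruption moves `carryover_fraction`
of month *a*'s observed volume into month *b* before ranking, truncation
and share computation. Identical config + seed yields byte-identical
files.

What the generator does **not** emulate: correlated noise across entities
or months, drug-name vocabulary drift, demographic structure within the
eligibility counts, ranking ties, or reporting-lag revisions. Passing
tests therefore demonstrate the pipeline's arithmetic and censoring
semantics, not robustness to every real-data pathology.

### Default scenario

The bundled default covers January 2016 – October 2024 (106 months),
matching the coverage window of the national dataset this pipeline
targets, with parameters loosely calibrated to published national
figures: ~1.57 million eligible persons with a slow decline (coverage
fell over the period), a CPI rising ~21% across the window, top-100
lists, `noise_cv = 0.05` (monthly totals of high-volume items are stable
at roughly the few-percent level), a May → June 2021 disruption with
carryover 0.8, ~4.8 million dispensings/month of unmodelled tail mass,
and nine entities: four proton-pump inhibitors with diverging trends, two
gabapentinoids with sharp unit-cost steps in April/May 2020 (reference
pricing), a lidocaine-style product restricted in late 2017, and two
winter-seasonal respiratory/anti-infective agents. Test fixtures use a
smaller four-year, five-entity variant of the same shape to keep the
suite fast.

## Numerical choices

- Values are kept at full float precision internally; rounding happens
  only at export (2 decimals for EUR and per-1,000 rates, integers for
  frequencies).
- Ranking-merge agreement uses a relative tolerance of 1e-6; published
  files that disagree beyond that raise a logged warning, not an error.
- Cost per prescribing at zero frequency is missing, not zero or
  infinity; a zero-valued parent makes a comparison month missing.
- Ties in synthetic ranking are broken by ATC code so output files are
  deterministic.
- Eligibility totals are integers (persons); the generator writes its
  drifting eligibility level rounded per month and the recorded truth
  uses the same rounded totals, keeping the rate oracle exact.

## Design notes

- The disruption correction is applied to raw frequency and cost before
  any ratio or rate, so all five metrics derive from one corrected pair;
  applying it after ratios would let the two months disagree across
  metrics.
- Proportions are reported as fractions in [0, 1], not percentages,
  matching how share-of-group figures are conventionally quoted.
- Costs default to nominal euros; inflation adjustment is opt-in
  (`DeriveOptions.adjust_inflation`), since published use of such data
  mixes both conventions and the choice should be visible in the call.
- HTML plot export embeds a static SVG figure (traces carry stable ids)
  in a minimal page; it is a lightweight inspectable artefact, not an
  interactive application.
- The CLI exposes the same pipeline (`simulate`, `ingest`, `series`,
  `compare`) for shell users; the library API is the primary surface.

## Limitations

- Only one scheme's file layout is handled per mapping profile; the
  shipped `zenodo_workbook` profile is a documented template that must be
  checked against the actual archived workbook before use.
- No DDD/PDD utilisation normalisation, no statistical trend testing
  (e.g. interrupted time-series regression), and no region- or
  practice-level analysis — the source data do not support them.
- Medication→ATC assignment is taken from the input files; the package
  does not embed the WHO ATC dictionary.
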