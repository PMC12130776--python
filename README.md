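# pharmtrends

Drug-utilisation time series from national pharmacy-claims open data.

Many national payers publish monthly open-data report tables on community
dispensing: the top-100 medications ranked by prescribing frequency and by
ingredient cost, plus complete totals per WHO ATC therapeutic group, along
with scheme-eligibility counts by area. In Ireland this is the HSE-PCRS
open data for the means-tested GMS scheme (roughly a third of the
population). These tables are valuable for pharmacoepidemiology and policy
evaluation — preferred-drug initiatives, reference pricing, reimbursement
restrictions, seasonality — but awkward to use raw: values are scattered
over hundreds of monthly files, lists are top-N censored, costs are
nominal euros, and one known transmission outage split a month's claims
across two reports.

`pharmtrends` is a library (plus a thin CLI) for exactly this class of
data. It is aimed at pharmacoepidemiologists, health-policy analysts and
data scientists who want reproducible series rather than a dashboard.

## What it computes

For an entity *i* (an ATC level-5 medication, level-2 therapeutic group or
level-1 physiological system) in month *t*, with dispensing frequency
*f_it*, ingredient cost *c_it* (EUR), scheme-eligible persons *E_t* and
consumer price index *P_t*:

| metric | definition |
|---|---|
| prescribing frequency | *f_it* |
| ingredient cost | *c_it* |
| cost per prescribing | *c_it / f_it* |
| prescribing rate | *1000 · f_it / E_t* |
| cost rate | *1000 · c_it / E_t* |

Cost-bearing metrics can be deflated to reference-month prices:
*c̃_it = c_it · P_ref / P_t*, with *ref* defaulting to the latest CPI month.

Further operations:

- **Censoring semantics** — months where a medication falls below the
  published top-N are *missing* (the true value is unknown but bounded by
  the Nth-ranked value), never zero.
- **Disruption correction** — for a configured month pair (a, b) where
  claims from *a* were transmitted in *b*, both observed values are
  replaced by their weighted mean (weights default to calendar days per
  month); a value observed for only one of the two months is left alone.
- **Hierarchy comparison** — the proportion of a parent entity's metric
  accounted for by a strict ATC descendant, *f_child,t / f_parent,t*, on
  the [0, 1] scale, with parent values taken from the complete group
  totals rather than reconstructed from censored children.
- **Seasonal profile** — per-calendar-month mean divided by overall mean,
  for spotting winter peaks.

A synthetic-data generator writes portal-style monthly CSV bundles from a
closed-form model (trend × seasonality × step changes, lognormal noise,
top-N truncation, eligibility drift, CPI inflation, disruption) together
with the analytic truth, so the entire pipeline is testable end to end
without any download.

## Worked example

```python
import tempfile
from pharmtrends import (Dataset, DeriveOptions, MetricName,
                         default_config, generate)

with tempfile.TemporaryDirectory() as workdir:
    generate(default_config(seed=42), workdir)   # portal-style CSV bundle
    dataset = Dataset.load(workdir)

    options = DeriveOptions(disruption=("2021-05", "2021-06"))
    rate = dataset.series("A02BC02", MetricName.PRESCRIBING_RATE, options)
    print(rate.points[0].value, rate.points[-1].value)

    share = dataset.comparison("A02BC02", "A02",
                               MetricName.PRESCRIBING_FREQUENCY, options)
    print(share.points[0].value, share.points[-1].value)
```

Output (seed 42):

```
pantoprazole prescribing rate 2016-01:  33.39 /1,000
pantoprazole prescribing rate 2024-10:  62.67 /1,000
pantoprazole  share of A02: 0.179 (2016-01) -> 0.247 (2024-10)
```

Pantoprazole's dispensing rate roughly doubles from ~33 to ~63 dispensings
per 1,000 eligible persons per month over nine years, and its share of all
drugs for acid-related disorders (ATC A02) climbs from 0.18 to 0.25 — the
kind of trajectory a preferred-drug policy evaluation looks for. The
scripts in `examples/` walk through simulation/ingest, metric derivation,
hierarchy comparison, and policy steps/censoring/seasonality, each
printing and explaining its numbers.

The same workflow is available from a shell:

```sh
pharmtrends simulate --out bundle/ --seed 42
pharmtrends series  --data bundle/ --entity A02BC02 \
    --metric prescribing_rate --disruption 2021-05,2021-06 --out rate.csv
pharmtrends compare --data bundle/ --child A02BC02 --parent A02 --out share.csv
```

## Layout

- `src/pharmtrends/` — `atc` (codes and hierarchy), `ingest` (readers and
  cleaning rules), `metrics` (series and derivations), `compare`
  (proportions, filtering, seasonality), `synthetic` (generator and
  ground truth), `dataset`/`interface`/`cli` (loading, export, plots,
  commands).
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
- `examples/` — narrative scripts, one per capability.
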