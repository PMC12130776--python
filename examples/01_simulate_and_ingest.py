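"""Generate a synthetic claims bundle and load it back as a dataset.

The generator writes the same monthly CSV report files a national claims
open-data portal publishes (top-N medication lists, therapeutic-group
totals, eligibility counts, a CPI series) plus a truth.json with the
closed-form series behind them.
"""

import tempfile

from pharmtrends import Dataset, default_config, generate

with tempfile.TemporaryDirectory() as workdir:
    config = default_config(seed=42)
    truth = generate(config, workdir)
    dataset = Dataset.load(workdir)
    summary = dataset.summary()

    print(f"months covered : {summary['months'][0]} .. {summary['months'][-1]}"
          f"  ({summary['n_months']} months)")
    print(f"medications    : {summary['n_medications']}")
    print(f"therapeutic groups: {summary['n_therapeutic_groups']}")
    print(f"eligible persons, first month: {truth.eligibility[dataset.months[0]]:,}")

# The counts confirm the bundle round-trips: every generated month was
# ingested, and the eligibility denominator is at the national GMS scale
# (~1.5 million persons).
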