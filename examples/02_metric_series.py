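"""Derive the five metrics for one medication, with disruption correction
and CPI inflation adjustment.

Prints pantoprazole's prescribing rate (dispensings per 1,000 eligible
persons) at the start and end of coverage, and its nominal vs
inflation-adjusted cost rate for the first month.
"""

import tempfile

from pharmtrends import (
    Dataset,
    DeriveOptions,
    MetricName,
    default_config,
    generate,
)

with tempfile.TemporaryDirectory() as workdir:
    generate(default_config(seed=42), workdir)
    dataset = Dataset.load(workdir)

    # correct the May->June 2021 transmission disruption before deriving
    options = DeriveOptions(disruption=("2021-05", "2021-06"))

    rate = dataset.series("A02BC02", MetricName.PRESCRIBING_RATE, options)
    first, last = rate.points[0], rate.points[-1]
    print(f"pantoprazole prescribing rate {first.month}: {first.value:6.2f} /1,000")
    print(f"pantoprazole prescribing rate {last.month}: {last.value:6.2f} /1,000")

    nominal = dataset.series("A02BC02", MetricName.COST_RATE, options)
    adjusted = dataset.series(
        "A02BC02", MetricName.COST_RATE,
        DeriveOptions(disruption=("2021-05", "2021-06"), adjust_inflation=True),
    )
    print(f"cost rate {first.month} nominal : EUR {nominal.points[0].value:7.2f} /1,000")
    print(f"cost rate {first.month} adjusted: EUR {adjusted.points[0].value:7.2f} /1,000")

# The rate roughly doubles over nine years (the configured upward trend),
# and the adjusted figure exceeds the nominal one because early-period
# euros are re-expressed at end-of-coverage prices.
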