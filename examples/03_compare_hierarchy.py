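"""Child-within-parent comparison across the ATC hierarchy.

Computes the proportion of all drugs for acid-related disorders (ATC A02)
accounted for by one proton-pump inhibitor, month by month — the package's
"compare" feature.
"""

import tempfile

from pharmtrends import Dataset, DeriveOptions, MetricName, default_config, generate

with tempfile.TemporaryDirectory() as workdir:
    generate(default_config(seed=42), workdir)
    dataset = Dataset.load(workdir)
    options = DeriveOptions(disruption=("2021-05", "2021-06"))

    for code, label in (("A02BC02", "pantoprazole"), ("A02BC05", "esomeprazole")):
        comp = dataset.comparison(code, "A02", MetricName.PRESCRIBING_FREQUENCY, options)
        first, last = comp.points[0], comp.points[-1]
        print(f"{label:13s} share of A02: {first.value:.3f} ({first.month}) "
              f"-> {last.value:.3f} ({last.month})")

# Proportions are on the [0, 1] scale. A rising share means the medication
# is growing faster than its therapeutic group as a whole — the signal a
# preferred-drug policy evaluation looks for.
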