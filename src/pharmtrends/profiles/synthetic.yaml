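# Column-mapping profile for the CSV dialect written by pharmtrends.synthetic.
entity_name: entity_name
atc_code: atc_code
frequency: frequency
pct_frequency: pct_frequency
ingredient_cost: ingredient_cost
pct_cost: pct_cost
month: month
area: area
count: count
sheet: 0
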