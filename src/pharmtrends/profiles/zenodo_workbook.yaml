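# Adapter profile template for the archived processed workbook that
# accompanies the national claims dashboard (XLSX, read from the first
# sheet by default).
#
# The exact sheet and header layout of that deposit is not documented in
# print; the header names below are a best-effort template and MUST be
# checked against the downloaded file before use (adjust the right-hand
# sides and `sheet` to match, then pass this file to ColumnMapping.load).
entity_name: Medication
atc_code: ATC Code
frequency: Prescribing Frequency
pct_frequency: "% Share of Prescriptions"
ingredient_cost: Ingredient Cost
pct_cost: "% Share of Cost"
month: Month
area: Area
count: Eligible Persons
sheet: 0
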