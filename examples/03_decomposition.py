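"""Kitagawa decomposition: how much of a rate change is demographic?

Constructs a country whose age structure shifts older between 2010 and 2021
while age-specific stillbirth risks improve, then splits the national rate
change into the composition effect (age-structure shift alone) and the rate
effect (within-age risk change alone).
"""

import pandas as pd

from stillbirth_trends import BirthTable, decompose_over_time, decompose_vs_reference

rows = []
design = {
    # year: (share per band, rate per 1000 per band)
    2010: ([0.30, 0.55, 0.15], [3.5, 2.8, 6.0]),
    2021: ([0.20, 0.52, 0.28], [3.6, 2.5, 4.4]),
}
for year, (shares, rates) in design.items():
    for band, share, rate in zip(["<25", "25-34", "35+"], shares, rates):
        births = 100_000 * share
        sb = births * rate / 1000
        rows.append({"country": "Beta", "year": year, "axis": "maternal_age",
                     "stratum": band, "stillbirths": sb, "live_births": births - sb})
table = BirthTable(data=pd.DataFrame(rows))

res = decompose_over_time(table, "Beta", "maternal_age", 2010, 2021)
print(f"rate 2010: {res.crude_rate_a:.3f}  rate 2021: {res.crude_rate_b:.3f} per 1000")
print(f"total change       {res.total_difference:+.3f} per 1000")
print(f"  composition part {res.composition_component:+.3f}  (aging of mothers alone)")
print(f"  rate part        {res.rate_component:+.3f}  (within-age risk change alone)")
print(res.per_stratum[["stratum", "composition", "rate"]].to_string(index=False))

# The aging of the maternal population alone would have *raised* the rate
# (positive composition part); falling within-age risks more than offset
# it.  The two parts always add exactly to the total change.
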