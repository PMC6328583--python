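"""Linear time trends of gene expression in cultured myocardium.

Each gene's culture-vs-fresh log2 expression ratio at days 8, 14, 24 and 35
is summarised by OLS: the intercept extrapolates the immediate (day-0)
response, slope x 35 the cumulative drift over five weeks of culture.
"""

import myoslice as ms
from myoslice.transcript import load_reference_table, trend_table

table = trend_table(load_reference_table(1))
print("strongest recovery trends among contractility genes:")
cols = ["gene", "intercept", "slope_x35", "trend"]
print(table[table.function == "Cardiomyocyte contractility"][cols]
      .head(4).to_string(index=False, float_format="%.2f"))

print("\nworked example MYH7 (beta-myosin heavy chain):")
b0, slope, s35 = ms.ols_trend((8, 14, 24, 35), (-3.76, -1.52, -2.64, 0.60))
print(f"  intercept {b0:.2f} (about 22-fold down at culture start), "
      f"slope x 35 = {s35:.2f} (recovering ~{2**s35:.0f}-fold over 5 weeks)")
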