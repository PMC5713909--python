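"""Survey-weighted crosstabs and chi-square contrasts.

First on simulated records, then reproducing a column of the published
county-wide table from its printed weighted counts alone.
"""

from trostar import SimulationConfig, simulate_county, weighted_chisq, weighted_crosstab
from trostar.descriptives import reproduce_printed_table

county = simulate_county(SimulationConfig(seed=1))

tab = weighted_crosstab(county.students, "grade")
stat, df, p = weighted_chisq(tab)
print("grade x current use (synthetic county):")
print(tab.to_frame().to_string())
print(f"\nPearson X2 = {stat:.2f}, df = {df}, p = {p:.4f}")
print("(weighted percentages; the statistic is computed on the table")
print(" rescaled to the unweighted n, so uniform weight scaling cancels)")

tab2, comparisons = reproduce_printed_table("cigarette", "sex")
print("\npublished sex x cigarette-use column percentages, recomputed from")
print("the printed weighted counts (printed -> recomputed):")
for cat, col, printed, recomputed, consistent in comparisons:
    note = "" if consistent else "   <- printed cell known to be internally inconsistent"
    print(f"  {cat:6s} {col:12s} {printed:5.1f} -> {recomputed:5.1f}{note}")
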