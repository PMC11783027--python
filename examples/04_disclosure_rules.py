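"""The two disclosure-control rules, on their own.

Counts are rounded to the nearest 10 (halves away from zero); percentages
are integers computed from the RAW numerator and denominator, never from
the rounded counts.  That is why a raw cell of 4 patients out of 50 prints
as "0 (8)": the count is suppressed but the percentage is honest.
"""

from cohortlens import disclose, disclosed_percent, round_count
from cohortlens.tables import make_table

for n in (0, 4, 5, 26_437, 33_480):
    print(f"round_count({n:>6}) = {round_count(n)}")

print()
for num, den in ((26_440, 33_480), (7_040, 33_480), (2_980, 6_400), (4, 50)):
    print(f"disclosed_percent({num:>6}, {den:>6}) = {disclosed_percent(num, den)}")

small = make_table("small cell", [("Age (years)", "Younger than 25")], ["x"],
                   {("Age (years)", "Younger than 25", "x"): 4},
                   {("Age (years)", "Younger than 25", "x"): 50})
cell = disclose(small).cells.iloc[0, 0]
print(f"\nraw 4 of 50 discloses as: {cell!r}")
print("A reader sees no count below 10 anywhere, yet every percentage "
      "reflects the true underlying ratio, so prevalence estimates carry "
      "no rounding bias.")
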