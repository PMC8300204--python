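"""Full synthetic campaign with Tukey-lettered treatment comparison.

Simulates a 6-day campaign of three lighting treatments whose ground
truth orders motility blue > green > red and gives only red a feeder
attraction, then prints the journal-style comparison tables: cells are
means with an uppercase letter comparing rows (periods) within a
treatment and a lowercase letter comparing treatments within a row.
Cells sharing a letter are not significantly different (Tukey, 5%).
"""

from hensight import anova_tukey
from hensight.pipeline import SeasonConfig, run_synthetic_season

season = run_synthetic_season(SeasonConfig(n_days=6, recording_s=30, seed=2))
units = season["units"]
print(f"{len(units)} recording means (3 treatments x 6 days x 2 periods)")
print()

for resp in ("unrest", "cluster"):
    tab = anova_tukey(units, resp, "period")
    print(f"{resp} index by period of day (treatment p = {tab.treatment_pvalue:.2e})")
    print(tab.formatted().to_string())
    print()

print("Distinct lowercase letters across a row mean the treatments differ;")
print("the ground-truth orderings (unrest blue>green>red, cluster red top)")
print("are recovered from the rendered frames alone.")
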