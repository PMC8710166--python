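"""Chamber dosimetry and LC50 from the five-group mortality design.

Converts each group's burned stick mass into a smoke concentration, then
estimates the median lethal concentration with Karber's closed form and
the Spearman–Karber trapezoid estimator.
"""

from moxatox import chamber_dose, karber_lc50, max_tolerated_dose, spearman_karber_lc50
from moxatox import datasets
from moxatox.dosimetry import ExposureChamber

chamber = ExposureChamber(volume_m3=0.2)
groups = datasets.exposure_groups()

print("group  sticks(g)   dose(g/m3)  deaths/n")
for row in groups.itertuples():
    dose = chamber_dose(row.stick_mass_g, datasets.SMOKE_RATE, chamber)
    print(f"  {row.group}    {row.stick_mass_g:8.2f}   {dose:9.3f}   {row.deaths}/{row.n}")

table = datasets.mortality_table()
k = karber_lc50(table)
sk = spearman_karber_lc50(table)
print(f"\nKarber LC50:          {k.lc50:.2f} g/m3  (se_log10 = {k.se_log10:.4f})")
print(f"Spearman-Karber LC50: {sk.lc50:.2f} g/m3")
print(f"max tolerated dose:   {max_tolerated_dose(table):.3f} g/m3")
for w in k.warnings:
    print(f"note: {w}")
print(f"published reference LC50 {datasets.PUBLISHED_LC50_G_PER_M3} g/m3 is not")
print("reproducible from this table under the closed form and is reported unverified.")
print("\nThe LC50 is the concentration expected to kill half the animals;")
print("the tolerated dose is the highest tested concentration with no deaths.")
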