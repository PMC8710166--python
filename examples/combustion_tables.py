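"""Moisture, ash and smoke-generation-rate tables for moxa sticks.

Recomputes the three bench-measurement tables from the bundled raw masses
and O2 readings: moisture from wet/dry mass pairs, ash on wet and dry
basis, and the mass-balance smoke rate under the table-consistent oxygen
convention.
"""

from moxatox import (
    AshMeasurement,
    CombustionConstants,
    CombustionRun,
    StickMeasurement,
    ash_content,
    moisture_content,
    smoke_generation_rate,
    summarize_measurements,
)
from moxatox import datasets

moist = datasets.moisture_measurements()
print("moisture content (% — absolute W1 / relative W2):")
w2_rows = []
for row in moist.itertuples():
    r = moisture_content(StickMeasurement(m0=row.initial_g, m1=row.final_g))
    w2_rows.append(r.w2 * 100)
    print(f"  stick {row.Index}: W1 = {r.w1 * 100:6.2f}   W2 = {r.w2 * 100:6.2f}")
w2_mean, w2_sd = summarize_measurements(w2_rows)
print(f"  relative moisture mean ± SD: {w2_mean:.2f} ± {w2_sd:.2f} %")

print("\nash content with W2 = 9.59% (% — absolute S1 / relative S2):")
for row in datasets.ash_measurements().itertuples():
    r = ash_content(AshMeasurement(a1=row.stick_g, a2=row.ash_g), w2=0.0959)
    print(f"  stick {row.Index}: S1 = {r.s1 * 100:5.2f}   S2 = {r.s2 * 100:5.2f}")

print("\nsmoke generation rate (% of burned mass released as smoke):")
consts = CombustionConstants()  # table-consistent oxygen term
for row in datasets.combustion_runs().itertuples():
    run = CombustionRun(m2=row.stick_g, c1_pct=row.o2_before_pct,
                        c2_pct=row.o2_after_pct, m4=row.ash_g)
    rate = smoke_generation_rate(run, 0.0959, consts)
    print(f"  run {row.Index} ({row.stick_g:5.2f} g burned): {rate * 100:.2f}")

print("\nAbout 84.5% of a burned stick's mass leaves as smoke; this rate")
print("converts stick mass into chamber smoke concentration downstream.")
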