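# moxatox

Acute inhalation-toxicity analysis of moxa smoke, as a tested, reusable
Python library.

Moxibustion burns compressed *Artemisia argyi* (mugwort) sticks next to the
skin, and the particulate-laden smoke raises an obvious safety question for
patients and practitioners who inhale it for hours.  `moxatox` implements
the full quantitative chain used to answer it in a rat whole-body exposure
study, for anyone who wants to re-run, audit or extend that arithmetic:

1. **Combustion characterisation** — moisture content
   (W₁ = (m₀−m₁)/m₁, W₂ = (m₀−m₁)/m₀), ash content
   (S₂ = A₂/A₁, S₁ = S₂/(1−W₂)) and the mass-balance smoke generation
   rate M₁/M₂ with M₁ = M₂(1−W₂) − M₄ + ρ·ΔC·V (ρ = 1.429 g/L O₂).
   Two oxygen-term conventions are exposed; the default (`table_consistent`,
   effective gas volume V/10) is the only reading that reproduces the
   published rate table, and the literal reading logs a warning.
2. **Chamber dosimetry** — dose (g/m³) = stick mass × smoke rate / chamber
   volume (0.2 m³ cabinet), plus organ indexes (mg organ / g body mass).
3. **Quantal lethality** — Karber's closed form
   lg LC₅₀ = X_m − i(ΣP − 0.5) and the Spearman–Karber trapezoid estimator
   Σ(P_{j+1}−P_j)(x_j+x_{j+1})/2 on log₁₀ doses, with the classical
   binomial standard error i·√(ΣP(1−P)/(n−1)), pooled-adjacent-violators
   monotonization, and the maximum tolerated (zero-mortality) dose.
4. **Clinical scaling** — room-to-chamber volume ratio (216:1 for a
   4 × 3 × 3.6 m treatment room) and the safety margin of the tolerated
   burn over a 2-hour clinical session.
5. **Expression screening** — per-gene log₂ fold change, Welch tests,
   Benjamini–Hochberg FDR, the |log₂FC| ≥ 1 & p < 0.05 screen, and
   2^−ΔΔCt qPCR quantification.
6. **Synthetic generators** — seeded generators for every input above,
   including a probit latent-tolerance mortality simulator and spiked
   expression matrices with ground truth, so the whole chain is testable
   offline.

One published number is deliberately *not* reproduced: the study's printed
LC₅₀ of 537.65 g/m³ does not follow from Karber's formula on its own
mortality table (the closed forms give 403.1 and 426.7 g/m³); the pipeline
reports it as an unverified reference value rather than matching it.

## Worked example

```python
from moxatox import chamber_dose, karber_lc50, spearman_karber_lc50, max_tolerated_dose
from moxatox import datasets
from moxatox.dosimetry import ExposureChamber

chamber = ExposureChamber(volume_m3=0.2)
print(chamber_dose(151.33, 0.8446, chamber))   # 639.06659 -> group A dose 639.067 g/m3

table = datasets.mortality_table()             # five groups, six rats each
print(karber_lc50(table).lc50)                 # 403.0954930994096
print(spearman_karber_lc50(table).lc50)        # 426.687661769315
print(max_tolerated_dose(table))               # 290.036
```

The first line converts group A's 151.33 g of burned sticks into the
chamber concentration 639.067 g/m³ (84.46% of burned mass becomes smoke,
diluted into 0.2 m³).  The two LC₅₀ estimates bracket the concentration
expected to kill half the animals; 290.036 g/m³ is the highest tested
concentration with no deaths, which scales to a 68.68× margin over a
standard clinical session (`examples/clinical_scaling.py`).

Each script in `examples/` exercises one capability end to end and prints
what the numbers mean: `combustion_tables.py`, `dose_and_lc50.py`,
`clinical_scaling.py`, `deg_screening.py`, `estimator_recovery.py`.

A thin CLI mirrors the library (`moxatox combustion|dose|lc50|screen|ddct|
simulate|fixtures|report`); exit codes are 0 success, 2 validation error,
3 estimation error.

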