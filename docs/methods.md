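# Methods

## Combustion mass balance

Moisture is measured by oven-drying a stick to constant weight at
103 ± 2 °C: the absolute content W₁ = (m₀ − m₁)/m₁ refers the lost water to
the dry mass, the relative content W₂ = (m₀ − m₁)/m₀ to the wet mass, so
W₁ ≥ W₂ with equality only for a bone-dry stick.  Ash content has the same
duality: S₂ = A₂/A₁ on the as-received stick and the dry-basis
S₁ = S₂/(1 − W₂), giving the exact identity S₁/S₂ = 1/(1 − W₂).

The smoke generation rate follows from mass conservation: the smoke mass
is everything burned that is neither moisture nor ash, plus the oxygen
drawn from the chamber atmosphere,

    M₁ = M₂(1 − W₂) − M₄ + M₅,   rate = M₁/M₂,
    M₅ = ρ · ΔC · V_gas,   ρ = 1.429 g/L.

**Oxygen-term convention.** Taking V_gas as the full 200 L chamber volume
(the `as_stated` convention) makes M₅ ≈ 1.43 g for a 0.5-point O₂ drop and
pushes run 1's rate to 96.69% — irreconcilable with the measured 84.62%.
The measured rate table is reproduced, to within rounding of every row,
only with an oxygen mass ten times smaller (`table_consistent`,
V_gas = V/10 = 20 L, M₅ = 0.143 g).  Both conventions are implemented
behind an explicit enum; `table_consistent` is the default and the literal
reading logs a warning.  The physical origin of the factor (an effective
gas volume, or a unit slip in the source measurement protocol) cannot be
determined from the available numbers and is documented rather than
resolved.

**Moisture applied per run.** The measurement protocol does not say
whether per-batch or mean moisture entered each combustion run; the
package applies the mean relative moisture W₂ = 9.59% to all runs.  This
reproduces run 1 exactly and runs 2–3 to within 0.02 percentage points at
the tables' 2-dp precision (per-batch values of ≈9.6% would close the
residual, but are not guessed).

All moisture/ash/rate values are fractions internally; percent formatting
(decimal half-up, matching how measurement tables round) happens only at
reporting boundaries, and the mean ± SD row of a rendered table summarises
the rendered (2-dp) rows, as printed tables conventionally do.  Sample SD
uses the n−1 denominator.

## Dosimetry and clinical scaling

The nominal chamber concentration is dose = mass × rate / volume with the
cabinet at 0.2 m³ and the propagated rate fixed at 0.8446 (the 4-dp value
the dosing design itself carries, configurable).  Volumes are m³ in this
layer and litres in the combustion layer; the conversion lives in a single
constant (`L_PER_M3`) so the units cannot silently mix.

Clinical scaling compares the chamber to a two-bed 4 × 3 × 3.6 m
moxibustion room (volume ratio 216:1).  The room's 2-hour stick
consumption defaults to 216 g — back-derived from the stated 216:1 ratio
and the stated equivalence "room session ≙ 1 g in the chamber", since the
protocol's own figures (200 g per two patients per 45 min) are internally
inconsistent; the value is overridable.  The safety margin is then
tolerated mass / (room consumption / volume ratio); with the defaults the
denominator is exactly 1 g, so the 68.68 g zero-mortality burn gives a
68.68× margin.

Organ index is 1000 × organ mass / body mass (mg/g).

## Quantal lethality

The latent-tolerance model: each animal has a lethal log₁₀ dose; group
mortality at dose d estimates the tolerance CDF at lg d.  Karber's closed
form lg LC₅₀ = X_m − i(ΣP − 0.5) presumes a geometric ladder with constant
log-spacing i.  The study's dose column is *not* geometric (adjacent
ratios 1.14–1.30), so the package uses the mean adjacent log₁₀ spacing
(i = 0.08577 for that table) and attaches a warning listing the per-pair
spacings; a fixed i may be supplied instead.  Spearman–Karber is the
companion estimator, Σ(P_{j+1} − P_j)(x_j + x_{j+1})/2, identical to
Karber on uniform monotone 0→1 ladders (an algebraic identity the suite
property-tests) and consistent for the tolerance mean under any symmetric
tolerance distribution.  Optional pooled-adjacent-violators monotonization
(weighted by group size) handles non-monotone mortality, behind an
explicit flag.  The standard error is the classical binomial form
i·√(Σ P(1−P)/(n−1)); extreme groups (P ∈ {0,1}) contribute nothing.

**The unverified published LC₅₀.** On the five-group table the closed
forms give 403.10 (Karber, mean spacing) and 426.69 g/m³
(Spearman–Karber); the published 537.65 g/m³ follows from neither under
any standard reading of the spacing (it would require i ≈ 0.032, matching
no adjacent-dose ratio).  The pipeline therefore reports the published
value as an unverified reference, with a logged warning, and never tunes
toward it.  The mortality table's published P² column is consistent with
squared mortality proportions; it plays no role in estimation and is not
consumed.

## Synthetic generators

All generators derive their random stream from
`SeedSequence([seed, generator_id])` with fixed per-generator ids, so one
global seed is bit-reproducible and adding a generator never perturbs
existing draws.

* **Stick measurements**: relative moisture ~ Normal(9.59%, 0.63 pp)
  truncated to (0, 1) — the spread of the measured moisture table — with
  m₀ uniform on 3.0–3.6 g (the measured mass range) and m₁ = m₀(1 − W₂).
* **Combustion runs**: M₂ and the O₂ drop are sampled in the measured
  regimes and the ash mass is back-solved so the mass balance returns the
  target rate exactly — a round-trip identity the suite asserts to
  machine precision.
* **Dose–mortality**: deaths ~ Binomial(n, F((lg d − μ)/σ)) with F the
  standard normal CDF (probit; logit optional).  Probit is the default
  because it is the classical assumption under which Karber/SK estimate
  the mean lethal log-dose.
* **Expression matrices**: log-normal values — per-sample log₂ noise
  (SD 0.25 by default, a typical between-replicate spread for normalized
  bulk expression) around gene baselines uniform on log₂ 3–8; spiked genes
  get an exact ±effect shift of the exposed-group log₂ mean, and the
  ground-truth labels are returned.  Log-normal (rather than
  negative-binomial counts) is a deliberate simplification: the screen
  consumes normalized values and the Welch-on-log₂ test stays calibrated,
  which the null-design false-positive test checks.  Passing tests on
  these matrices show the screening arithmetic is correct, not that the
  Welch substitute reproduces count-model (DESeq-style) inference on real
  read counts.

## Estimator-recovery study

The recovery study simulates 500 bioassays from a probit model
(μ = lg 500, σ = 0.1) on a five-level geometric ladder spanning μ ± 2σ
with 50 animals per group.  Spearman–Karber is only defined when observed
mortality spans 0 to 1; endpoint groups sit at expected mortality
0.023/0.977, so most replicates are unscorable and are skipped (~90% at
these sizes).  Because the ladder is log-symmetric about μ, the skipping
is symmetric under P → 1−P and leaves the conditional mean at μ, so the
bracket-conditioned average is an unbiased check; the suite requires
|bias| < 0.01 log₁₀ units, and typical runs give ~0.001 with ~50 scored
replicates.

## DEG screening

Fold change is log₂((mean_exposed + c)/(mean_control + c)) with
pseudocount c = 1 guarding all-zero genes.  Per-gene testing is a
two-sided Welch unequal-variance t on log₂(value + 1) (transform
switchable); this is a self-contained substitute for count-model testing,
not a reimplementation of it, and externally computed p-values are
accepted everywhere a screen runs.  BH adjustment is the standard step-up
q_k = min_{j≥k}(m·p_(j)/j) capped at 1.  The screen is inclusive on the
fold-change boundary (|log₂FC| ≥ 1) and strict on significance
(p < α = 0.05), screening raw p by default or BH-adjusted p in FDR mode —
both published phrasings of the threshold exist, so both modes are
exposed and neither is asserted as canonical.  The published DEG counts
per comparison (486/877/186) require the study's undeposited raw reads
and are carried as reference numbers only.  2^−ΔΔCt is the textbook
relative-quantification formula with ΔCt = Ct(target) − Ct(reference).

## Numerical and interface choices

* Comparisons against published table values happen only in tests, at the
  tables' printed precision (half-ulp tolerance at 2 or 3 dp), never
  silently inside the pipeline.
* Mortality tables sort by ascending dose on construction; duplicate
  doses are rejected; estimation contracts (≥3 groups for Karber,
  bracketed mortality, n ≥ 2 for the SE) raise typed errors that the CLI
  maps to exit codes 2 (validation) and 3 (estimation).
* Study reports serialize to sorted-key, full-precision JSON with no
  timestamps, so identical inputs give byte-identical reports; every
  derived block carries a provenance entry naming the operation and its
  inputs.
* Problem sizes in the test suite and acceptance script (500-replicate
  recovery at n = 50/group, 1000-gene matrices at n = 6/group) match the
  study conditions where stated and otherwise are chosen so binomial/CLT
  error bands are an order of magnitude tighter than the asserted
  tolerances.

## Known limitations

* The combustion model is a static mass balance: no combustion chemistry,
  particle-size distributions or drying kinetics.
* Dosimetry is nominal total-mass-over-volume: no aerosol deposition,
  time-resolved concentration or oxygen-depletion dynamics.
* Lethality offers closed-form estimators only; probit/logit maximum
  likelihood with covariates is out of scope.
* The expression stage starts from a normalized matrix: no read
  alignment, FPKM computation, dispersion modelling or enrichment
  analysis.
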