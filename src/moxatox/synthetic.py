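"""Synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure its consuming stage
assumes, so the full chain (combustion → dosimetry → lethality → DEG
screen) is testable without any external data:

* stick measurements with Gaussian moisture noise around the measured
  regime (mean relative moisture 9.59%, SD 0.63 percentage points),
* combustion runs back-solved so the mass balance recovers an exact
  target smoke rate (round-trip fixtures),
* quantal mortality from a latent log10-dose tolerance model
  (probit by default, logit optionally): deaths ~ Binomial(n, F((lg d − μ)/σ)),
* expression matrices with log-normal null genes and a spiked
  differentially-expressed fraction at an exact log2 effect size, with
  the ground-truth labels returned alongside.

Seeding: one global integer seed fans out to fixed per-generator
substreams (``SeedSequence([seed, generator_id])``), so adding a new
generator never perturbs fixtures drawn by existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .combustion import CombustionConstants, CombustionRun, StickMeasurement, smoke_generation_rate
from .deg_screen import ExpressionMatrix
from .errors import ValidationError
from .lethality import MortalityTable

# fixed substream ids; append-only so existing fixtures stay stable
_STREAM_IDS = {
    "stick_measurements": 1,
    "combustion_runs": 2,
    "dose_mortality": 3,
    "expression_matrix": 4,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_IDS[stream]]))


@dataclass(frozen=True)
class ToleranceModel:
    """Latent lethal log10-dose model: each animal's tolerance is
    mu + sigma * Z with Z standard Normal (probit link, the classical
    assumption under which Karber/Spearman-Karber estimate mu) or
    standard logistic (logit link)."""

    mu: float
    sigma: float
    link: str = "probit"

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValidationError(f"sigma must be > 0, got {self.sigma!r}")
        if self.link not in ("probit", "logit"):
            raise ValidationError(f"link must be 'probit' or 'logit', got {self.link!r}")

    def mortality_at(self, dose: "float | np.ndarray") -> "float | np.ndarray":
        """Expected mortality F((lg dose − mu)/sigma) at a given dose."""
        z = (np.log10(dose) - self.mu) / self.sigma
        if self.link == "probit":
            return stats.norm.cdf(z)
        return stats.logistic.cdf(z)

    def geometric_doses(self, n_levels: int = 5, span_sigmas: float = 2.0) -> np.ndarray:
        """Geometric dose ladder spanning mu ± span_sigmas·sigma in log10."""
        lg = np.linspace(self.mu - span_sigmas * self.sigma,
                         self.mu + span_sigmas * self.sigma, n_levels)
        return 10.0 ** lg


def gen_stick_measurements(
    n: int,
    mean_w2: float = 0.0959,
    noise_sd: float = 0.0063,
    m0_range: tuple[float, float] = (3.0, 3.6),
    seed: int = 0,
) -> list[StickMeasurement]:
    """Stick wet/dry mass pairs with relative moisture ~ Normal, truncated
    to (0, 1): m0 uniform in ``m0_range``, m1 = m0·(1 − W2)."""
    if not (0 < mean_w2 < 1):
        raise ValidationError(f"mean_w2 must lie in (0, 1), got {mean_w2!r}")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if not (0 < m0_range[0] <= m0_range[1]):
        raise ValidationError(f"invalid m0_range {m0_range!r}")
    rng = _rng(seed, "stick_measurements")
    out: list[StickMeasurement] = []
    for _ in range(n):
        w2 = mean_w2 if noise_sd == 0 else rng.normal(mean_w2, noise_sd)
        while not (0 < w2 < 1):
            w2 = rng.normal(mean_w2, noise_sd)
        m0 = rng.uniform(*m0_range)
        out.append(StickMeasurement(m0=m0, m1=m0 * (1.0 - w2)))
    return out


def gen_combustion_runs(
    n: int,
    true_rate: float = 0.8446,
    w2: float = 0.0959,
    consts: CombustionConstants | None = None,
    m2_range: tuple[float, float] = (10.0, 40.0),
    delta_c_pct_range: tuple[float, float] = (0.4, 1.8),
    seed: int = 0,
    max_retries: int = 100,
) -> list[CombustionRun]:
    """Combustion runs back-solved so the mass balance recovers
    ``true_rate`` exactly (round-trip identity).

    M2 and the O2 drop are sampled; the ash mass is then solved from
    M4 = M2·(1 − w2) + M5 − rate·M2.  Parameter combinations implying
    negative ash are resampled, with an error after bounded retries.
    """
    if not (0 < true_rate < 1):
        raise ValidationError(f"true_rate must lie in (0, 1), got {true_rate!r}")
    if consts is None:
        consts = CombustionConstants()
    rng = _rng(seed, "combustion_runs")
    out: list[CombustionRun] = []
    for _ in range(n):
        for attempt in range(max_retries):
            m2 = rng.uniform(*m2_range)
            dc = rng.uniform(*delta_c_pct_range)
            c1 = rng.uniform(20.8, 21.4)
            m5 = consts.rho * (dc / 100.0) * consts.effective_gas_volume_l
            m4 = m2 * (1.0 - w2) + m5 - true_rate * m2
            if 0 < m4 < m2:
                out.append(CombustionRun(m2=m2, c1_pct=c1, c2_pct=c1 - dc, m4=m4))
                break
        else:
            raise ValidationError(
                "gen_combustion_runs: could not sample a run with non-negative "
                f"ash after {max_retries} retries (parameters too extreme)"
            )
    return out


def gen_dose_mortality(
    model: ToleranceModel,
    doses,
    n_per_group: int = 6,
    seed: int = 0,
) -> MortalityTable:
    """Quantal mortality draws: deaths_j ~ Binomial(n, F((lg d_j − μ)/σ))."""
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValidationError("doses must be strictly positive")
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    rng = _rng(seed, "dose_mortality")
    p = np.asarray(model.mortality_at(doses), dtype=float)
    deaths = rng.binomial(n_per_group, p)
    return MortalityTable(
        tuple(doses), tuple([n_per_group] * len(doses)), tuple(int(k) for k in deaths)
    )


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of a Spearman–Karber estimator-recovery study."""

    mean_log10_estimate: float
    bias_log10: float
    sd_log10: float
    n_used: int
    n_skipped: int


def sk_recovery_study(
    model: ToleranceModel,
    n_levels: int = 5,
    span_sigmas: float = 2.0,
    n_per_group: int = 50,
    n_reps: int = 500,
    seed: int = 0,
) -> RecoveryResult:
    """Repeatedly simulate quantal tables from ``model`` and average the
    Spearman–Karber log10 estimate.

    Replicates whose endpoint groups do not reach mortality exactly 0 and 1
    cannot be scored by Spearman–Karber and are skipped; because the dose
    ladder is log-symmetric about mu, this conditioning is itself symmetric
    and leaves the conditional mean at mu.  Non-monotone replicates are
    monotonized by pooled-adjacent-violators.
    """
    from .errors import EstimationError
    from .lethality import spearman_karber_lc50

    doses = model.geometric_doses(n_levels, span_sigmas)
    estimates = []
    skipped = 0
    for rep in range(n_reps):
        table = gen_dose_mortality(model, doses, n_per_group, seed=seed + rep)
        try:
            estimates.append(
                spearman_karber_lc50(table, monotonize=True).log10_lc50
            )
        except EstimationError:
            skipped += 1
    if not estimates:
        raise ValidationError(
            "sk_recovery_study: no replicate spanned mortality 0 to 1; "
            "widen the dose ladder or increase n_per_group"
        )
    mean = float(np.mean(estimates))
    return RecoveryResult(
        mean_log10_estimate=mean,
        bias_log10=mean - model.mu,
        sd_log10=float(np.std(estimates)),
        n_used=len(estimates),
        n_skipped=skipped,
    )


@dataclass(frozen=True)
class SpikeDesign:
    """Design of a spiked expression matrix.

    ``effect_log2fc`` is the exact log2 group-mean difference given to each
    spiked gene (positive for up, negative applied for down).  Null genes
    share a log-normal baseline with per-sample log2 noise ``noise_sd``.
    """

    n_genes: int = 1000
    n_up: int = 7
    n_down: int = 5
    effect_log2fc: float = 2.0
    n_per_group: int = 6
    noise_sd: float = 0.25
    baseline_log2_range: tuple[float, float] = (3.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValidationError("n_up + n_down cannot exceed n_genes")
        if self.effect_log2fc < 0:
            raise ValidationError("effect_log2fc must be >= 0")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def gen_expression_matrix(design: SpikeDesign) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Spiked expression matrix plus its ground-truth labels.

    Values are 2**(baseline + effect + noise): log-normal on the
    expression scale, with spiked genes' exposed-group log2 mean shifted
    by exactly ±effect_log2fc.  Returns (matrix, truth) where ``truth``
    has columns ``gene_id`` and ``spike`` in {"up", "down", "null"}.
    """
    rng = _rng(design.seed, "expression_matrix")
    g, m = design.n_genes, design.n_per_group
    gene_ids = [f"gene_{i:05d}" for i in range(g)]
    spike = np.array(
        ["up"] * design.n_up + ["down"] * design.n_down
        + ["null"] * (g - design.n_up - design.n_down)
    )
    rng.shuffle(spike)
    baseline = rng.uniform(*design.baseline_log2_range, size=g)
    effect = np.where(spike == "up", design.effect_log2fc,
                      np.where(spike == "down", -design.effect_log2fc, 0.0))
    log2_control = baseline[:, None] + rng.normal(0.0, design.noise_sd, size=(g, m))
    log2_exposed = (baseline + effect)[:, None] + rng.normal(
        0.0, design.noise_sd, size=(g, m)
    )
    samples = [f"ctrl_{j+1}" for j in range(m)] + [f"expo_{j+1}" for j in range(m)]
    values = pd.DataFrame(
        np.column_stack([2.0 ** log2_control, 2.0 ** log2_exposed]),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=samples,
    )
    groups = pd.Series(["control"] * m + ["exposed"] * m, index=samples, name="group")
    truth = pd.DataFrame({"gene_id": gene_ids, "spike": spike})
    return ExpressionMatrix(values=values, groups=groups), truth
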