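"""Quantal dose–mortality analysis: Karber and Spearman–Karber LC50.

A quantal bioassay exposes groups of animals to a ladder of doses and
records deaths.  Under the classical tolerance model each animal carries a
latent lethal log10 dose; group mortality estimates the tolerance CDF at
the group's log dose, and the LC50 is the tolerance mean.

Two closed-form estimators are implemented:

* **Karber's formula**  lg LC50 = Xm − i·(ΣP − 0.5), where Xm is the log10
  of the largest dose, P the per-group mortality proportions and i the
  log10 spacing of adjacent doses.  The formula presumes a geometric dose
  ladder (constant i); for non-geometric designs this module uses the mean
  adjacent log10 spacing and attaches a warning listing the per-pair
  spacings.

* **Spearman–Karber** — the trapezoid sum Σ (P_{j+1} − P_j)(x_j + x_{j+1})/2
  over ascending log10 doses x_j, the nonparametric estimator of the mean
  log tolerance.  It coincides with Karber's formula exactly on a
  geometric ladder with monotone 0→1 mortality, and is consistent for the
  tolerance mean under any symmetric tolerance distribution.  Optional
  pooled-adjacent-violators monotonization handles noisy, non-monotone
  mortality.

The standard error attached to either estimate is the classical binomial
form se = i·sqrt(Σ P_j(1 − P_j)/(n_j − 1)).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError, ValidationError


class LC50Method(str, enum.Enum):
    KARBER = "karber"
    SPEARMAN_KARBER = "spearman_karber"


@dataclass(frozen=True)
class MortalityTable:
    """Ordered quantal design: per-group (dose g/m^3, group size, deaths).

    Groups are sorted by ascending dose on construction regardless of
    input order; doses must be strictly positive and unique.
    """

    doses: tuple[float, ...]
    n: tuple[int, ...]
    deaths: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.doses) == len(self.n) == len(self.deaths)):
            raise ValidationError("doses, n and deaths must have equal length")
        if len(self.doses) == 0:
            raise ValidationError("mortality table is empty")
        for j, (d, nj, kj) in enumerate(zip(self.doses, self.n, self.deaths)):
            if not (d > 0):
                raise ValidationError(f"dose must be > 0 in group {j}, got {d!r}")
            if nj <= 0:
                raise ValidationError(f"n must be a positive integer in group {j}")
            if not (0 <= kj <= nj):
                raise ValidationError(
                    f"deaths ({kj}) must lie in [0, n={nj}] in group {j}"
                )
        if len(set(self.doses)) != len(self.doses):
            raise ValidationError("doses must be unique")
        order = np.argsort(self.doses)
        object.__setattr__(self, "doses", tuple(float(self.doses[i]) for i in order))
        object.__setattr__(self, "n", tuple(int(self.n[i]) for i in order))
        object.__setattr__(self, "deaths", tuple(int(self.deaths[i]) for i in order))

    @classmethod
    def from_records(cls, records: "list[tuple[float, int, int]]") -> "MortalityTable":
        doses, n, deaths = zip(*records) if records else ((), (), ())
        return cls(tuple(doses), tuple(n), tuple(deaths))

    @property
    def mortality(self) -> np.ndarray:
        """Per-group mortality proportions P_j, ascending dose order."""
        return np.asarray(self.deaths, dtype=float) / np.asarray(self.n, dtype=float)

    @property
    def log10_doses(self) -> np.ndarray:
        return np.log10(np.asarray(self.doses, dtype=float))

    def scaled(self, factor: float) -> "MortalityTable":
        """Same design with every dose multiplied by ``factor``."""
        if not (factor > 0):
            raise ValidationError(f"factor must be > 0, got {factor!r}")
        return MortalityTable(
            tuple(d * factor for d in self.doses), self.n, self.deaths
        )


@dataclass(frozen=True)
class LC50Estimate:
    """LC50 point estimate on both scales, with method and diagnostics."""

    log10_lc50: float
    method: LC50Method
    i_used: float
    se_log10: float | None = None
    warnings: tuple[str, ...] = ()

    @property
    def lc50(self) -> float:
        return 10.0 ** self.log10_lc50


_SPACING_RTOL = 1e-9


def _mean_log_spacing(table: MortalityTable) -> tuple[float, list[str]]:
    gaps = np.diff(table.log10_doses)
    i = float(gaps.mean())
    warnings: list[str] = []
    if not np.allclose(gaps, i, rtol=1e-6, atol=1e-9):
        warnings.append(
            "non-uniform log10 dose spacing; using mean adjacent spacing "
            f"i = {i:.5f} (per-pair spacings: "
            + ", ".join(f"{g:.5f}" for g in gaps)
            + ")"
        )
    return i, warnings


def _check_bracketed(table: MortalityTable) -> None:
    p = table.mortality
    if p.max() == 0.0 or p.min() == 1.0:
        raise EstimationError(
            "LC50 not bracketed: mortality must span below and above 50% "
            f"(observed proportions {list(np.round(p, 4))})"
        )


def karber_lc50(
    table: MortalityTable,
    i_strategy: "float | str" = "mean_log_spacing",
    with_se: bool = True,
) -> LC50Estimate:
    """Karber's closed-form LC50: lg LC50 = Xm − i·(ΣP − 0.5).

    Parameters
    ----------
    i_strategy : ``"mean_log_spacing"`` (default) computes i as the mean
        of adjacent log10 dose ratios; a float supplies a fixed i.
    with_se : attach the classical binomial standard error when every
        group has n >= 2.
    """
    if len(table.doses) < 3:
        raise ValidationError(
            f"karber_lc50 needs at least 3 dose groups, got {len(table.doses)}"
        )
    _check_bracketed(table)
    if isinstance(i_strategy, str):
        if i_strategy != "mean_log_spacing":
            raise ValidationError(f"unknown i_strategy {i_strategy!r}")
        i, warns = _mean_log_spacing(table)
    else:
        i = float(i_strategy)
        if not (i > 0):
            raise ValidationError(f"i must be > 0, got {i!r}")
        warns = []
    xm = float(table.log10_doses[-1])
    sum_p = float(table.mortality.sum())
    log_lc50 = xm - i * (sum_p - 0.5)
    se = karber_se(table, i) if with_se and min(table.n) >= 2 else None
    return LC50Estimate(
        log10_lc50=log_lc50,
        method=LC50Method.KARBER,
        i_used=i,
        se_log10=se,
        warnings=tuple(warns),
    )


def _pava_monotone(p: np.ndarray, weights: np.ndarray) -> np.ndarray:
    # isotonic (non-decreasing in dose) weighted least-squares fit
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    return iso.fit_transform(np.arange(p.size), p, sample_weight=weights)


def spearman_karber_lc50(
    table: MortalityTable,
    monotonize: bool = False,
    with_se: bool = True,
) -> LC50Estimate:
    """Spearman–Karber trapezoid estimator of the mean log10 tolerance.

    Requires mortality 0 at the lowest and 1 at the highest dose (after
    optional pooled-adjacent-violators monotonization when ``monotonize``
    is set).  Non-monotone input without monotonization is allowed but
    flagged with a warning.
    """
    if len(table.doses) < 2:
        raise ValidationError("spearman_karber_lc50 needs at least 2 dose groups")
    p = table.mortality
    warns: list[str] = []
    if monotonize:
        pooled = _pava_monotone(p, np.asarray(table.n, dtype=float))
        if not np.allclose(pooled, p):
            warns.append("mortality was non-monotone; pooled-adjacent-violators applied")
        p = pooled
    elif np.any(np.diff(p) < 0):
        warns.append(
            "mortality is non-monotone in dose; consider monotonize=True"
        )
    if p[0] != 0.0 or p[-1] != 1.0:
        raise EstimationError(
            "Spearman-Karber requires mortality 0 at the lowest dose and 1 at "
            f"the highest (observed {list(np.round(p, 4))}); the tolerance "
            "distribution is not fully spanned"
        )
    x = table.log10_doses
    dp = np.diff(p)
    mid = (x[:-1] + x[1:]) / 2.0
    log_lc50 = float(np.sum(dp * mid))
    i, spacing_warns = _mean_log_spacing(table)
    warns.extend(spacing_warns)
    se = karber_se(table, i) if with_se and min(table.n) >= 2 else None
    return LC50Estimate(
        log10_lc50=log_lc50,
        method=LC50Method.SPEARMAN_KARBER,
        i_used=i,
        se_log10=se,
        warnings=tuple(warns),
    )


def karber_se(table: MortalityTable, i: float) -> float:
    """Classical binomial SE of the Karber/SK log10 LC50.

    se = i * sqrt( Σ_j P_j (1 − P_j) / (n_j − 1) ).  Groups at mortality 0
    or 1 contribute nothing; every group must have n >= 2.
    """
    if min(table.n) < 2:
        raise ValidationError("karber_se requires n >= 2 in every group")
    p = table.mortality
    n = np.asarray(table.n, dtype=float)
    return float(i * math.sqrt(float(np.sum(p * (1.0 - p) / (n - 1.0)))))


def max_tolerated_dose(table: MortalityTable) -> float:
    """Largest administered dose with zero observed mortality (g/m^3)."""
    zero = [d for d, k in zip(table.doses, table.deaths) if k == 0]
    if not zero:
        raise EstimationError(
            "no tolerated dose observed: every group had at least one death"
        )
    return max(zero)
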