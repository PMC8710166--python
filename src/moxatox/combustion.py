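"""Basic combustion parameters of moxa sticks.

Moxa sticks (compressed *Artemisia argyi* floss) are characterised before
smoke-exposure experiments by three bench measurements:

* **moisture content** — oven-dry a stick and compare masses.  Two
  conventions coexist: the *absolute* content W1 expresses the water lost
  relative to the dry mass, the *relative* content W2 relative to the wet
  mass, so W1 >= W2 always.
* **ash content** — burn a stick and weigh the residue; again an absolute
  (dry-basis) S1 and a relative (wet-basis) S2 form.
* **smoke generation rate** — by mass conservation, the smoke released per
  gram of stick burned is everything that is neither moisture nor ash,
  plus the mass of oxygen consumed from the chamber atmosphere:

      M1 = M2·(1 − W2) − M4 + M5,        rate = M1 / M2

  with M2 the stick mass burned, M4 the ash mass, and M5 = ρ·ΔC·V the
  oxygen mass drawn from the chamber (ρ = 1.429 g/L, ΔC the drop in O₂
  volume fraction, V the gas volume).

The oxygen term has two published conventions, selected by
:class:`OxygenConvention`.  Taken literally with the full 200 L chamber
volume (``AS_STATED``) the term is ten times larger than the value that is
consistent with published measurement tables; ``TABLE_CONSISTENT`` (the
default) uses an effective gas volume of V/10 (20 L for the 200 L chamber),
the only reading that reproduces those tables.  A warning is logged
whenever the literal convention is used.

All fractions (moisture, ash, rate) are held as fractions in [0, 1]
internally; percent formatting happens only at I/O boundaries.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Density of O2 at the chamber's working conditions, g/L.
O2_DENSITY_G_PER_L = 1.429

#: Exposure-chamber gas volume, litres.
CHAMBER_VOLUME_L = 200.0


class OxygenConvention(str, enum.Enum):
    """How the oxygen mass term M5 of the smoke mass balance is computed.

    ``AS_STATED``        M5 = rho * dC * V   (formula taken literally)
    ``TABLE_CONSISTENT`` M5 = rho * dC * V/10 (effective gas volume; the
                         only reading consistent with published rate tables)
    """

    AS_STATED = "as_stated"
    TABLE_CONSISTENT = "table_consistent"


def _require_positive(name: str, value: float) -> None:
    if not (value > 0):
        raise ValidationError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class StickMeasurement:
    """Wet/dry mass pair for one stick: initial mass ``m0`` and oven-dry
    mass ``m1``, both in grams."""

    m0: float
    m1: float

    def __post_init__(self) -> None:
        _require_positive("m0", self.m0)
        _require_positive("m1", self.m1)
        if self.m1 > self.m0:
            raise ValidationError(
                f"m1 (dry mass, {self.m1}) cannot exceed m0 (initial mass, {self.m0})"
            )


@dataclass(frozen=True)
class MoistureResult:
    """Absolute (w1, dry-basis) and relative (w2, wet-basis) moisture
    contents as fractions."""

    w1: float
    w2: float


@dataclass(frozen=True)
class AshMeasurement:
    """Stick mass before burning ``a1`` and ash mass after ``a2`` (g)."""

    a1: float
    a2: float

    def __post_init__(self) -> None:
        _require_positive("a1", self.a1)
        if self.a2 < 0:
            raise ValidationError(f"a2 (ash mass) must be >= 0, got {self.a2!r}")
        if self.a2 >= self.a1:
            raise ValidationError(
                f"a2 (ash mass, {self.a2}) must be smaller than a1 (stick mass, {self.a1})"
            )


@dataclass(frozen=True)
class AshResult:
    """Absolute (s1, dry-basis) and relative (s2, wet-basis) ash contents
    as fractions."""

    s1: float
    s2: float


@dataclass(frozen=True)
class CombustionRun:
    """One chamber combustion run.

    Parameters
    ----------
    m2 : stick mass burned, g.
    c1_pct, c2_pct : O2 concentration before/after burning, in percentage
        points of the chamber atmosphere (e.g. 21.4).
    m4 : ash mass produced, g.
    """

    m2: float
    c1_pct: float
    c2_pct: float
    m4: float

    def __post_init__(self) -> None:
        _require_positive("m2", self.m2)
        if self.m4 < 0:
            raise ValidationError(f"m4 (ash mass) must be >= 0, got {self.m4!r}")
        if self.m4 >= self.m2:
            raise ValidationError(
                f"m4 (ash mass, {self.m4}) must be smaller than m2 (stick mass, {self.m2})"
            )
        if self.c2_pct > self.c1_pct:
            raise ValidationError(
                f"c2_pct (O2 after, {self.c2_pct}) cannot exceed c1_pct (O2 before, {self.c1_pct})"
            )

    @property
    def delta_c_fraction(self) -> float:
        """O2 concentration drop as a fraction (percentage points / 100)."""
        return (self.c1_pct - self.c2_pct) / 100.0


@dataclass(frozen=True)
class CombustionConstants:
    """Physical constants entering the smoke mass balance."""

    rho: float = O2_DENSITY_G_PER_L
    volume_l: float = CHAMBER_VOLUME_L
    convention: OxygenConvention = OxygenConvention.TABLE_CONSISTENT

    def __post_init__(self) -> None:
        _require_positive("rho", self.rho)
        _require_positive("volume_l", self.volume_l)

    @property
    def effective_gas_volume_l(self) -> float:
        if self.convention is OxygenConvention.AS_STATED:
            return self.volume_l
        return self.volume_l / 10.0


def moisture_content(m: StickMeasurement) -> MoistureResult:
    """Absolute and relative moisture content of one stick.

    w1 = (m0 - m1)/m1 (dry basis), w2 = (m0 - m1)/m0 (wet basis); both
    returned as fractions.  w1 >= w2 always, with equality iff no water
    was lost.
    """
    lost = m.m0 - m.m1
    return MoistureResult(w1=lost / m.m1, w2=lost / m.m0)


def ash_content(a: AshMeasurement, w2: float) -> AshResult:
    """Absolute (dry-basis) and relative ash content of one stick.

    s2 = a2/a1 on the as-received stick; s1 = a2/(a1*(1 - w2)) refers the
    same ash to the stick's dry mass, so s1/s2 = 1/(1-w2) exactly.

    Parameters
    ----------
    w2 : relative moisture content of the sticks, as a fraction in [0, 1).
    """
    if not (0 <= w2 < 1):
        raise ValidationError(f"w2 must lie in [0, 1), got {w2!r}")
    s2 = a.a2 / a.a1
    s1 = s2 / (1.0 - w2)
    return AshResult(s1=s1, s2=s2)


def oxygen_mass(run: CombustionRun, consts: CombustionConstants) -> float:
    """Mass of O2 (g) consumed during a run under the chosen convention."""
    if consts.convention is OxygenConvention.AS_STATED:
        logger.warning(
            "oxygen convention 'as_stated' uses the full %.0f L chamber volume; "
            "this is 10x the value consistent with published rate tables "
            "(use 'table_consistent' to reproduce them)",
            consts.volume_l,
        )
    return consts.rho * run.delta_c_fraction * consts.effective_gas_volume_l


def smoke_generation_rate(
    run: CombustionRun,
    w2: float,
    consts: CombustionConstants | None = None,
) -> float:
    """Fraction of burned stick mass released as smoke.

    rate = (M2·(1 − w2) − M4 + M5) / M2 with M5 the consumed-oxygen mass
    under ``consts.convention``.  Returns a fraction; raises
    :class:`EstimationError`-free :class:`ValidationError` on a negative
    smoke mass ("implausible combustion run").
    """
    if consts is None:
        consts = CombustionConstants()
    if not (0 <= w2 < 1):
        raise ValidationError(f"w2 must lie in [0, 1), got {w2!r}")
    m5 = oxygen_mass(run, consts)
    m1 = run.m2 * (1.0 - w2) - run.m4 + m5
    if m1 < 0:
        raise ValidationError(
            f"implausible combustion run: smoke mass M1 = {m1:.4g} g is negative"
        )
    return m1 / run.m2


def summarize_measurements(values: list[float] | np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n−1 denominator) of a column.

    Requires at least two values; this is the "mean ± SD" row appended to
    every measurement table.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError(
            f"summarize_measurements needs at least 2 values, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError("summarize_measurements: values must be finite")
    return float(arr.mean()), float(arr.std(ddof=1))
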