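"""Chamber smoke dosimetry and clinical room-equivalence scaling.

The exposure design burns a known stick mass inside a sealed chamber of
known volume; the nominal smoke concentration ("dose") is

    dose (g/m^3) = stick_mass (g) * smoke_rate / chamber_volume (m^3)

with smoke_rate the mass fraction of stick converted to smoke (see
:mod:`moxatox.combustion`).  Downstream, a tolerated chamber dose is put in
clinical terms by comparing the chamber to a moxibustion treatment room:
the room-to-chamber volume ratio converts the room's 2-hour stick
consumption into its chamber-equivalent mass, and the safety margin is the
tolerated mass expressed in multiples of that equivalent.

Units are deliberately split across layers: this module works in cubic
metres, the combustion mass balance in litres; the conversion lives in a
single constant so the two never mix silently.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: Litres per cubic metre — the one place the two volume units meet.
L_PER_M3 = 1000.0

#: Smoke generation rate the dosing design propagates (mass fraction).
DEFAULT_SMOKE_RATE = 0.8446

#: Clinical 2-hour stick consumption (g) for a standard two-bed
#: moxibustion room; back-derived from the stated room/chamber volume
#: ratio of 216:1 and the stated 1 g chamber equivalence.
DEFAULT_CLINICAL_STICK_MASS_PER_2H = 216.0


def _require_positive(name: str, value: float) -> None:
    if not (value > 0):
        raise ValidationError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class ExposureChamber:
    """Sealed exposure chamber; the study cabinet is 0.2 m^3 (200 L)."""

    volume_m3: float = 0.2

    def __post_init__(self) -> None:
        _require_positive("volume_m3", self.volume_m3)

    @property
    def volume_l(self) -> float:
        return self.volume_m3 * L_PER_M3


@dataclass(frozen=True)
class ClinicalRoom:
    """Moxibustion treatment room (default: 4 x 3 x 3.6 m, two beds)."""

    length_m: float = 4.0
    width_m: float = 3.0
    height_m: float = 3.6
    stick_mass_per_2h: float = DEFAULT_CLINICAL_STICK_MASS_PER_2H

    def __post_init__(self) -> None:
        for name in ("length_m", "width_m", "height_m", "stick_mass_per_2h"):
            _require_positive(name, getattr(self, name))

    @property
    def volume_m3(self) -> float:
        return self.length_m * self.width_m * self.height_m


@dataclass(frozen=True)
class ExposureGroup:
    """One dose group of the acute-toxicity design."""

    label: str
    n: int
    stick_mass: float
    deaths: int
    body_weight_mean: float | None = None
    body_weight_sd: float | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError(f"n must be a positive integer, got {self.n!r}")
        _require_positive("stick_mass", self.stick_mass)
        if not (0 <= self.deaths <= self.n):
            raise ValidationError(
                f"deaths ({self.deaths}) must lie in [0, n={self.n}] for group {self.label!r}"
            )

    @property
    def mortality(self) -> float:
        return self.deaths / self.n


def chamber_dose(
    stick_mass: float,
    smoke_rate: float = DEFAULT_SMOKE_RATE,
    chamber: ExposureChamber | None = None,
) -> float:
    """Nominal smoke concentration (g/m^3) from burning ``stick_mass`` g.

    dose = stick_mass * smoke_rate / volume.  Linear in mass and rate,
    inverse in volume.
    """
    if chamber is None:
        chamber = ExposureChamber()
    _require_positive("stick_mass", stick_mass)
    if not (0 < smoke_rate <= 1):
        raise ValidationError(f"smoke_rate must lie in (0, 1], got {smoke_rate!r}")
    return stick_mass * smoke_rate / chamber.volume_m3


def organ_index(organ_mass_g: float, body_mass_g: float) -> float:
    """Organ index: organ weight per body weight, reported in mg/g."""
    _require_positive("organ_mass_g", organ_mass_g)
    _require_positive("body_mass_g", body_mass_g)
    if organ_mass_g >= body_mass_g:
        raise ValidationError(
            f"organ_mass_g ({organ_mass_g}) must be smaller than body_mass_g ({body_mass_g})"
        )
    return 1000.0 * organ_mass_g / body_mass_g


def volume_ratio(room: ClinicalRoom, chamber: ExposureChamber) -> float:
    """Room-to-chamber volume ratio (dimensionless; 216 for the defaults)."""
    return room.volume_m3 / chamber.volume_m3


def clinical_equivalent_mass(room: ClinicalRoom, chamber: ExposureChamber) -> float:
    """Chamber stick mass producing the same smoke concentration as the
    room's 2-hour clinical consumption (1 g for the defaults)."""
    return room.stick_mass_per_2h / volume_ratio(room, chamber)


def clinical_safety_margin(
    tolerated_mass: float,
    room: ClinicalRoom | None = None,
    chamber: ExposureChamber | None = None,
) -> float:
    """How many times the tolerated chamber burn exceeds the clinical dose.

    tolerated_mass / (room stick mass per 2 h scaled down by the volume
    ratio).  With the default room and chamber the clinical equivalent is
    exactly 1 g, so the margin equals the tolerated mass in grams.
    """
    if room is None:
        room = ClinicalRoom()
    if chamber is None:
        chamber = ExposureChamber()
    _require_positive("tolerated_mass", tolerated_mass)
    return tolerated_mass / clinical_equivalent_mass(room, chamber)
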