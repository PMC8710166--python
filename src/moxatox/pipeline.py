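"""End-to-end study pipeline: combustion → dosimetry → lethality (+ DEG).

:func:`run_full_analysis` chains the stages on CSV inputs (or the bundled
study tables) and returns a :class:`StudyReport` whose every derived
number carries a provenance entry naming the operation and inputs that
produced it.  Reports serialize to deterministic JSON (sorted keys, full
precision, no timestamps), so two runs on identical inputs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from . import combustion as comb
from . import datasets, dosimetry, io, lethality
from ._util import round_half_up
from .deg_screen import ScreenCriteria, differential_expression
from .errors import ValidationError

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class StudyConfig:
    """All tunables of the analysis chain, defaulting to the study values."""

    chamber_volume_m3: float = 0.2
    room_length_m: float = 4.0
    room_width_m: float = 3.0
    room_height_m: float = 3.6
    clinical_stick_mass_per_2h: float = 216.0
    smoke_rate_source: str = "fixed"  # "fixed" | "computed"
    fixed_smoke_rate: float = datasets.SMOKE_RATE
    oxygen_convention: str = "table_consistent"
    relative_moisture_w2: float = datasets.MEAN_RELATIVE_MOISTURE
    i_strategy: str = "mean_log_spacing"
    min_abs_log2fc: float = 1.0
    alpha: float = 0.05
    use_adjusted_p: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smoke_rate_source not in ("fixed", "computed"):
            raise ValidationError(
                f"smoke_rate_source must be 'fixed' or 'computed', got {self.smoke_rate_source!r}"
            )
        comb.OxygenConvention(self.oxygen_convention)  # raises on bad value

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def chamber(self) -> dosimetry.ExposureChamber:
        return dosimetry.ExposureChamber(volume_m3=self.chamber_volume_m3)

    @property
    def room(self) -> dosimetry.ClinicalRoom:
        return dosimetry.ClinicalRoom(
            length_m=self.room_length_m,
            width_m=self.room_width_m,
            height_m=self.room_height_m,
            stick_mass_per_2h=self.clinical_stick_mass_per_2h,
        )

    @property
    def combustion_constants(self) -> comb.CombustionConstants:
        return comb.CombustionConstants(
            volume_l=self.chamber_volume_m3 * dosimetry.L_PER_M3,
            convention=comb.OxygenConvention(self.oxygen_convention),
        )


@dataclass
class StudyReport:
    """Nested dict of results plus a flat provenance trail."""

    sections: dict
    provenance: list
    warnings: list

    def to_json(self) -> str:
        payload = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "sections": self.sections,
            "provenance": self.provenance,
            "warnings": self.warnings,
        }
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def _record(provenance: list, name: str, value, operation: str, inputs: dict):
    provenance.append(
        {"name": name, "operation": operation, "inputs": inputs}
    )
    return value


def run_full_analysis(
    config: StudyConfig | None = None,
    moisture_csv=None,
    ash_csv=None,
    combustion_csv=None,
    exposure_csv=None,
    expression_csv=None,
    sample_sheet_csv=None,
) -> StudyReport:
    """Run the full chain; paths default to the bundled study tables.

    Any stage's validation error propagates annotated with the stage name.
    """
    config = config or StudyConfig()
    provenance: list = []
    warnings: list = []
    sections: dict = {}

    # --- combustion: moisture ---
    stage = "combustion/moisture"
    try:
        if moisture_csv is not None:
            sticks = io.read_moisture_csv(moisture_csv)
        else:
            df = datasets.moisture_measurements()
            sticks = [
                comb.StickMeasurement(m0=r.initial_g, m1=r.final_g)
                for r in df.itertuples(index=False)
            ]
        moist = [comb.moisture_content(m) for m in sticks]
        # rows rendered at printed precision; the mean ± SD row summarises
        # the rendered rows, as measurement tables conventionally do
        w1_pct = [round_half_up(r.w1 * 100, 2) for r in moist]
        w2_pct = [round_half_up(r.w2 * 100, 2) for r in moist]
        w1_mean, w1_sd = comb.summarize_measurements(w1_pct)
        w2_mean, w2_sd = comb.summarize_measurements(w2_pct)
        sections["moisture"] = {
            "w1_pct": w1_pct,
            "w2_pct": w2_pct,
            "w1_mean_pct": round_half_up(w1_mean, 2),
            "w1_sd_pct": round_half_up(w1_sd, 2),
            "w2_mean_pct": round_half_up(w2_mean, 2),
            "w2_sd_pct": round_half_up(w2_sd, 2),
        }
        _record(provenance, "moisture", sections["moisture"], "combustion.moisture_content",
                {"n_sticks": len(sticks)})
    except ValidationError as e:
        raise ValidationError(f"[{stage}] {e}") from e

    # --- combustion: ash ---
    stage = "combustion/ash"
    try:
        if ash_csv is not None:
            ashes = io.read_ash_csv(ash_csv)
        else:
            df = datasets.ash_measurements()
            ashes = [
                comb.AshMeasurement(a1=r.stick_g, a2=r.ash_g)
                for r in df.itertuples(index=False)
            ]
        w2_used = config.relative_moisture_w2
        ash = [comb.ash_content(a, w2_used) for a in ashes]
        s1_pct = [round_half_up(r.s1 * 100, 2) for r in ash]
        s2_pct = [round_half_up(r.s2 * 100, 2) for r in ash]
        s1_mean, s1_sd = comb.summarize_measurements(s1_pct)
        s2_mean, s2_sd = comb.summarize_measurements(s2_pct)
        sections["ash"] = {
            "w2_used": w2_used,
            "s1_pct": s1_pct,
            "s2_pct": s2_pct,
            "s1_mean_pct": round_half_up(s1_mean, 2),
            "s1_sd_pct": round_half_up(s1_sd, 2),
            "s2_mean_pct": round_half_up(s2_mean, 2),
            "s2_sd_pct": round_half_up(s2_sd, 2),
        }
        _record(provenance, "ash", sections["ash"], "combustion.ash_content",
                {"n_sticks": len(ashes), "w2": w2_used})
    except ValidationError as e:
        raise ValidationError(f"[{stage}] {e}") from e

    # --- combustion: smoke rate ---
    stage = "combustion/smoke_rate"
    try:
        if combustion_csv is not None:
            runs = io.read_combustion_csv(combustion_csv)
        else:
            df = datasets.combustion_runs()
            runs = [
                comb.CombustionRun(
                    m2=r.stick_g, c1_pct=r.o2_before_pct, c2_pct=r.o2_after_pct, m4=r.ash_g
                )
                for r in df.itertuples(index=False)
            ]
        consts = config.combustion_constants
        rates = [comb.smoke_generation_rate(r, config.relative_moisture_w2, consts) for r in runs]
        rate_pct = [round_half_up(r * 100, 2) for r in rates]
        rate_mean, rate_sd = comb.summarize_measurements(rate_pct)
        sections["smoke_rate"] = {
            "convention": config.oxygen_convention,
            "rate_pct": rate_pct,
            "rate_mean_pct": round_half_up(rate_mean, 2),
            "rate_sd_pct": round_half_up(rate_sd, 2),
        }
        rate_mean /= 100.0  # fraction, for the 'computed' smoke-rate source
        _record(provenance, "smoke_rate", sections["smoke_rate"],
                "combustion.smoke_generation_rate",
                {"n_runs": len(runs), "convention": config.oxygen_convention})
    except ValidationError as e:
        raise ValidationError(f"[{stage}] {e}") from e

    # --- dosimetry ---
    stage = "dosimetry"
    try:
        if exposure_csv is not None:
            groups = io.read_exposure_csv(exposure_csv)
        else:
            df = datasets.exposure_groups()
            groups = [
                dosimetry.ExposureGroup(
                    label=r.group, n=int(r.n), stick_mass=float(r.stick_mass_g),
                    deaths=int(r.deaths),
                    body_weight_mean=float(r.body_weight_mean_g),
                    body_weight_sd=float(r.body_weight_sd_g),
                )
                for r in df.itertuples(index=False)
            ]
        smoke_rate = (
            config.fixed_smoke_rate
            if config.smoke_rate_source == "fixed"
            else rate_mean
        )
        chamber = config.chamber
        doses = [dosimetry.chamber_dose(g.stick_mass, smoke_rate, chamber) for g in groups]
        sections["dose_table"] = {
            "smoke_rate": smoke_rate,
            "chamber_volume_m3": chamber.volume_m3,
            "groups": [
                {
                    "group": g.label,
                    "stick_mass_g": g.stick_mass,
                    "dose_g_per_m3": round_half_up(d, 3),
                    "n": g.n,
                    "deaths": g.deaths,
                    "mortality": round(g.mortality, 4),
                }
                for g, d in zip(groups, doses)
            ],
        }
        _record(provenance, "dose_table", sections["dose_table"],
                "dosimetry.chamber_dose",
                {"smoke_rate": smoke_rate, "volume_m3": chamber.volume_m3})
    except ValidationError as e:
        raise ValidationError(f"[{stage}] {e}") from e

    # --- lethality ---
    stage = "lethality"
    try:
        table = lethality.MortalityTable.from_records(
            [(round_half_up(d, 3), g.n, g.deaths) for g, d in zip(groups, doses)]
        )
        i_strategy = config.i_strategy
        if i_strategy not in ("mean_log_spacing",):
            i_strategy = float(i_strategy)
        karber = lethality.karber_lc50(table, i_strategy=i_strategy)
        sk = lethality.spearman_karber_lc50(table)
        mtd = lethality.max_tolerated_dose(table)
        warnings.extend(karber.warnings)
        warnings.extend(w for w in sk.warnings if w not in warnings)
        note = (
            f"published LC50 reference {datasets.PUBLISHED_LC50_G_PER_M3} g/m^3 is "
            "UNVERIFIED: it does not follow from Karber's formula on this "
            f"mortality table (computed Karber {karber.lc50:.2f}, "
            f"Spearman-Karber {sk.lc50:.2f} g/m^3)"
        )
        warnings.append(note)
        logger.warning(note)
        sections["lethality"] = {
            "karber": {
                "lc50_g_per_m3": karber.lc50,
                "log10_lc50": karber.log10_lc50,
                "i_used": karber.i_used,
                "se_log10": karber.se_log10,
            },
            "spearman_karber": {
                "lc50_g_per_m3": sk.lc50,
                "log10_lc50": sk.log10_lc50,
                "se_log10": sk.se_log10,
            },
            "max_tolerated_dose_g_per_m3": mtd,
            "published_lc50_reference_g_per_m3": datasets.PUBLISHED_LC50_G_PER_M3,
            "published_lc50_verified": False,
        }
        _record(provenance, "lethality", sections["lethality"],
                "lethality.karber_lc50+spearman_karber_lc50+max_tolerated_dose",
                {"n_groups": len(table.doses)})
    except ValidationError as e:
        raise ValidationError(f"[{stage}] {e}") from e

    # --- clinical scaling ---
    stage = "clinical_scaling"
    try:
        room, chamber = config.room, config.chamber
        vr = dosimetry.volume_ratio(room, chamber)
        tolerated_mass = max(
            (g.stick_mass for g in groups if g.deaths == 0), default=None
        )
        scaling = {"volume_ratio": vr,
                   "clinical_stick_mass_per_2h_g": room.stick_mass_per_2h,
                   "clinical_equivalent_mass_g": dosimetry.clinical_equivalent_mass(room, chamber)}
        if tolerated_mass is not None:
            scaling["tolerated_stick_mass_g"] = tolerated_mass
            scaling["safety_margin"] = dosimetry.clinical_safety_margin(
                tolerated_mass, room, chamber
            )
        sections["clinical_scaling"] = scaling
        _record(provenance, "clinical_scaling", scaling,
                "dosimetry.volume_ratio+clinical_safety_margin",
                {"room_m3": room.volume_m3, "chamber_m3": chamber.volume_m3})
    except ValidationError as e:
        raise ValidationError(f"[{stage}] {e}") from e

    # --- optional DEG screen ---
    if expression_csv is not None:
        stage = "deg_screen"
        try:
            mat = io.read_expression(expression_csv, sample_sheet_csv)
            criteria = ScreenCriteria(
                min_abs_log2fc=config.min_abs_log2fc,
                alpha=config.alpha,
                use_adjusted=config.use_adjusted_p,
            )
            screen = differential_expression(mat, criteria)
            sections["deg_screen"] = {
                "criteria": {
                    "min_abs_log2fc": criteria.min_abs_log2fc,
                    "alpha": criteria.alpha,
                    "use_adjusted": criteria.use_adjusted,
                },
                "counts": screen.counts,
                "up": sorted(screen.up),
                "down": sorted(screen.down),
            }
            _record(provenance, "deg_screen", sections["deg_screen"],
                    "deg_screen.differential_expression",
                    {"n_genes": int(mat.values.shape[0])})
        except ValidationError as e:
            raise ValidationError(f"[{stage}] {e}") from e

    return StudyReport(sections=sections, provenance=provenance, warnings=warnings)


def materialize_fixtures(outdir, seed: int = 0) -> dict:
    """Write the bundled study tables and one synthetic matrix as the CSV
    dialects the pipeline reads; returns {name: path}."""
    from . import synthetic

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    df = datasets.moisture_measurements()[["initial_g", "final_g"]]
    paths["moisture"] = outdir / "moisture.csv"
    df.to_csv(paths["moisture"], index=False)

    df = datasets.ash_measurements()[["stick_g", "ash_g"]]
    paths["ash"] = outdir / "ash.csv"
    df.to_csv(paths["ash"], index=False)

    df = datasets.combustion_runs()[
        ["stick_g", "o2_before_pct", "o2_after_pct", "ash_g"]
    ]
    paths["combustion"] = outdir / "combustion.csv"
    df.to_csv(paths["combustion"], index=False)

    df = datasets.exposure_groups()[
        ["group", "n", "stick_mass_g", "deaths", "body_weight_mean_g", "body_weight_sd_g"]
    ]
    paths["exposure"] = outdir / "exposure.csv"
    df.to_csv(paths["exposure"], index=False)

    io.write_mortality_csv(
        datasets.mortality_table(), outdir / "mortality.csv",
        labels=["E", "D", "C", "B", "A"],
    )
    paths["mortality"] = outdir / "mortality.csv"

    mat, truth = synthetic.gen_expression_matrix(synthetic.SpikeDesign(seed=seed))
    paths["expression"] = outdir / "expression.csv"
    paths["samples"] = outdir / "samples.csv"
    io.write_expression(mat, paths["expression"], paths["samples"])
    truth.to_csv(outdir / "expression_truth.csv", index=False)
    paths["expression_truth"] = outdir / "expression_truth.csv"
    return paths
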