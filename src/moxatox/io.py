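"""CSV dialects read and written by the pipeline.

All files are headered, comma-separated, UTF-8, period decimal separator:

* moisture:   ``initial_g,final_g``
* ash:        ``stick_g,ash_g``
* combustion: ``stick_g,o2_before_pct,o2_after_pct,ash_g``
* exposure:   ``group,n,stick_mass_g,deaths[,body_weight_mean_g,body_weight_sd_g]``
* mortality:  ``group,dose_g_per_m3,n,deaths`` (dose may be omitted and
  filled from stick mass via dosimetry)
* expression: first column gene id, remaining columns samples, plus a
  two-column sample sheet ``sample,group``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .combustion import AshMeasurement, CombustionRun, StickMeasurement
from .deg_screen import ExpressionMatrix
from .dosimetry import ExposureGroup
from .errors import ValidationError
from .lethality import MortalityTable


def _read_csv(path, required: tuple[str, ...], kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{kind} file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{kind} file {path} contains no rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{kind} file {path} missing columns {missing}")
    return df


def read_moisture_csv(path) -> list[StickMeasurement]:
    df = _read_csv(path, ("initial_g", "final_g"), "moisture")
    return [
        StickMeasurement(m0=row.initial_g, m1=row.final_g)
        for row in df.itertuples(index=False)
    ]


def read_ash_csv(path) -> list[AshMeasurement]:
    df = _read_csv(path, ("stick_g", "ash_g"), "ash")
    return [AshMeasurement(a1=row.stick_g, a2=row.ash_g) for row in df.itertuples(index=False)]


def read_combustion_csv(path) -> list[CombustionRun]:
    df = _read_csv(
        path, ("stick_g", "o2_before_pct", "o2_after_pct", "ash_g"), "combustion"
    )
    return [
        CombustionRun(
            m2=row.stick_g,
            c1_pct=row.o2_before_pct,
            c2_pct=row.o2_after_pct,
            m4=row.ash_g,
        )
        for row in df.itertuples(index=False)
    ]


def read_exposure_csv(path) -> list[ExposureGroup]:
    df = _read_csv(path, ("group", "n", "stick_mass_g", "deaths"), "exposure")
    groups = []
    for row in df.itertuples(index=False):
        groups.append(
            ExposureGroup(
                label=str(row.group),
                n=int(row.n),
                stick_mass=float(row.stick_mass_g),
                deaths=int(row.deaths),
                body_weight_mean=float(row.body_weight_mean_g)
                if "body_weight_mean_g" in df.columns
                else None,
                body_weight_sd=float(row.body_weight_sd_g)
                if "body_weight_sd_g" in df.columns
                else None,
            )
        )
    return groups


def read_mortality_csv(path) -> MortalityTable:
    df = _read_csv(path, ("dose_g_per_m3", "n", "deaths"), "mortality")
    return MortalityTable.from_records(
        [
            (float(r.dose_g_per_m3), int(r.n), int(r.deaths))
            for r in df.itertuples(index=False)
        ]
    )


def read_expression(matrix_path, sample_sheet_path) -> ExpressionMatrix:
    """Expression matrix (CSV or TSV by extension) + ``sample,group`` sheet."""
    matrix_path = Path(matrix_path)
    sep = "\t" if matrix_path.suffix in (".tsv", ".tab", ".txt") else ","
    values = pd.read_csv(matrix_path, sep=sep, index_col=0)
    sheet = _read_csv(sample_sheet_path, ("sample", "group"), "sample sheet")
    groups = pd.Series(sheet["group"].values, index=sheet["sample"].values)
    return ExpressionMatrix(values=values, groups=groups)


def write_mortality_csv(table: MortalityTable, path, labels=None) -> None:
    labels = labels or [f"g{j+1}" for j in range(len(table.doses))]
    pd.DataFrame(
        {
            "group": labels,
            "dose_g_per_m3": table.doses,
            "n": table.n,
            "deaths": table.deaths,
        }
    ).to_csv(path, index=False)


def write_expression(mat: ExpressionMatrix, matrix_path, sample_sheet_path) -> None:
    mat.values.to_csv(matrix_path)
    pd.DataFrame({"sample": mat.groups.index, "group": mat.groups.values}).to_csv(
        sample_sheet_path, index=False
    )
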