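"""Bundled study measurement tables.

Small printed tables from the acute moxa-smoke inhalation study, entered
verbatim so the full analysis chain can be exercised without any download:
stick moisture and ash measurements, chamber combustion runs, the
five-group (A–E, six rats each) quantal mortality design, and lung organ
indexes.  Raw per-animal organ weights were never published, only group
means ± SD, so the organ-index table carries summaries.

The printed LC50 of 537.65 g/m^3 is kept here strictly as a published
reference value: it is not reproducible from the mortality table under
Karber's formula with any standard reading of the dose spacing, and the
pipeline reports it as unverified rather than matching it.
"""

from __future__ import annotations

import pandas as pd

from .dosimetry import ClinicalRoom, ExposureChamber
from .lethality import MortalityTable

#: Mean relative moisture content (fraction) used for all combustion runs.
MEAN_RELATIVE_MOISTURE = 0.0959

#: Smoke generation rate propagated into dosimetry (mass fraction).
SMOKE_RATE = 0.8446

#: Published LC50 reference value (g/m^3); documented as non-reproducible
#: from the mortality table below — see the lethality module.
PUBLISHED_LC50_G_PER_M3 = 537.65

STUDY_CHAMBER = ExposureChamber(volume_m3=0.2)
STUDY_ROOM = ClinicalRoom()  # 4 x 3 x 3.6 m, 216 g sticks per 2 h


def moisture_measurements() -> pd.DataFrame:
    """Six stick wet/dry mass pairs with the published moisture contents (%)."""
    return pd.DataFrame(
        {
            "initial_g": [3.03, 3.56, 3.25, 3.48, 3.42, 3.12],
            "final_g": [2.73, 3.25, 2.95, 3.15, 3.09, 2.79],
            "published_w1_pct": [10.99, 9.54, 10.17, 10.48, 10.68, 11.83],
            "published_w2_pct": [9.90, 8.71, 9.23, 9.48, 9.65, 10.58],
        },
        index=pd.RangeIndex(1, 7, name="no"),
    )


def ash_measurements() -> pd.DataFrame:
    """Six stick/ash mass pairs with the published ash contents (%)."""
    return pd.DataFrame(
        {
            "stick_g": [3.46, 3.37, 3.69, 3.52, 3.35, 3.53],
            "ash_g": [0.25, 0.24, 0.26, 0.25, 0.24, 0.25],
            "published_s1_pct": [7.99, 7.88, 7.79, 7.86, 7.92, 7.83],
            "published_s2_pct": [7.23, 7.12, 7.05, 7.10, 7.16, 7.08],
        },
        index=pd.RangeIndex(1, 7, name="no"),
    )


def combustion_runs() -> pd.DataFrame:
    """Three chamber combustion runs with published smoke rates (%)."""
    return pd.DataFrame(
        {
            "stick_g": [10.66, 24.32, 39.94],
            "o2_before_pct": [21.4, 20.9, 21.4],
            "o2_after_pct": [20.9, 20.0, 19.8],
            "ash_g": [0.76, 1.73, 2.84],
            "published_rate_pct": [84.62, 84.33, 84.43],
        },
        index=pd.RangeIndex(1, 4, name="no"),
    )


PUBLISHED_MEAN_RATE_PCT = 84.46


def exposure_groups() -> pd.DataFrame:
    """Acute-toxicity design: five groups of six rats, descending dose."""
    return pd.DataFrame(
        {
            "group": ["A", "B", "C", "D", "E"],
            "n": [6, 6, 6, 6, 6],
            "stick_mass_g": [151.33, 128.06, 112.51, 86.41, 68.68],
            "published_dose_g_per_m3": [639.067, 540.797, 475.130, 364.909, 290.036],
            "deaths": [6, 6, 4, 1, 0],
            "body_weight_mean_g": [307.62, 318.97, 361.99, 310.51, 339.67],
            "body_weight_sd_g": [7.05, 16.62, 9.75, 8.38, 9.97],
        }
    )


def mortality_table() -> MortalityTable:
    """The five-group quantal design as a :class:`MortalityTable`
    (doses taken at their published 3-dp values)."""
    df = exposure_groups()
    return MortalityTable.from_records(
        list(zip(df["published_dose_g_per_m3"], df["n"], df["deaths"]))
    )


def organ_index_summary() -> pd.DataFrame:
    """Published lung-index summaries (mg lung / g body mass) per group."""
    return pd.DataFrame(
        {
            "group": ["control", "A", "B", "C", "D", "E"],
            "n": [6, 6, 6, 6, 6, 6],
            "stick_mass_g": [None, 151.33, 128.06, 112.51, 86.41, 68.68],
            "lung_index_mean": [4.93, 7.67, 7.17, 5.58, 6.40, 5.23],
            "lung_index_sd": [0.57, 1.56, 1.68, 1.21, 2.29, 0.51],
        }
    )


def deg_count_summary() -> pd.DataFrame:
    """Published DEG counts per comparison (|log2FC| >= 1, P < 0.05).

    Reproducing these requires the study's raw sequencing reads, which were
    never deposited; the table is reference-only.
    """
    return pd.DataFrame(
        {
            "comparison": ["control_vs_A", "control_vs_B", "control_vs_E"],
            "total": [486, 877, 186],
            "up": [286, 400, 108],
            "down": [200, 477, 78],
        }
    )
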