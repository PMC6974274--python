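"""Packaged concordance tables and example study sets.

The two cohorts bundled here are the development cohort (a tertiary-centre
diabetic population, with the subgroup of patients with eGFR ≥60
ml/min/1.73 m² and a negative dipstick test that parameterises the baseline
cost model) and an independent external validation cohort.  The development
tables are full 3×3 cross-tabulations; the validation cohort and the dipstick
comparisons are available only as dichotomised 2×2 counts.

The meta-analysis study set bundled here is *illustrative* — synthetic
hazard-ratio inputs in the plausible range for albuminuria-vs-normoalbuminuria
outcome risks in diabetes — intended for demonstrating the pooling interface,
not as a reconstruction of any published forest plot.
"""

from __future__ import annotations

import numpy as np

from .accuracy import ConcordanceTable
from .meta import StudyEffect, effect_from_ci

__all__ = [
    "all_diabetes_table",
    "development_subgroup_table",
    "validation_all_table",
    "validation_subgroup_table",
    "dipstick_all_table",
    "dipstick_egfr60_table",
    "TABLE_SENSITIVITIES",
    "illustrative_studies",
]


def all_diabetes_table() -> ConcordanceTable:
    """Development cohort, all diabetic patients (n = 1,881)."""
    return ConcordanceTable(
        counts=np.array([[664, 408, 9], [52, 350, 78], [0, 17, 303]]),
        label="development: all diabetes",
    )


def development_subgroup_table() -> ConcordanceTable:
    """Development cohort, eGFR ≥60 and dipstick-negative subgroup (n = 1,110).

    This is the subgroup whose screening proportions parameterise the baseline
    cost model: quantitative-negative 917/1,110, semi-quantitative-negative
    615/1,110, false negatives 36 among 615 strip negatives, true positives
    157 among 495 strip positives.
    """
    return ConcordanceTable(
        counts=np.array([[579, 333, 5], [36, 142, 8], [0, 2, 5]]),
        label="development: eGFR>=60, dipstick-negative",
    )


def validation_all_table() -> ConcordanceTable:
    """External validation cohort, all diabetic patients (n = 431), dichotomised."""
    return ConcordanceTable.from_dichotomous(
        tn=214, fp=106, fn=18, tp=93, label="validation: all diabetes"
    )


def validation_subgroup_table() -> ConcordanceTable:
    """External validation cohort, eGFR ≥60 and dipstick-negative subgroup (n = 301)."""
    return ConcordanceTable.from_dichotomous(
        tn=187, fp=68, fn=8, tp=38, label="validation: eGFR>=60, dipstick-negative"
    )


def dipstick_all_table() -> ConcordanceTable:
    """Dipstick proteinuria vs quantitative uACR, all diabetic patients (n = 1,881).

    Reconstructed from the published screening-efficacy fractions (sensitivity
    65.6%, false positives 5.0 per 100 screened); the dichotomised margins are
    what the accuracy metrics consume.
    """
    # 800 quantitative positives as in the full cohort; 0.656*800 ≈ 525
    return ConcordanceTable.from_dichotomous(
        tn=1081 - 94, fp=94, fn=275, tp=525, label="development: dipstick, all"
    )


def dipstick_egfr60_table() -> ConcordanceTable:
    """Dipstick vs quantitative uACR, eGFR ≥60 subgroup (n = 1,369), reconstructed."""
    # 0.527 sensitivity on 296 quantitative positives ≈ 156 true positives
    return ConcordanceTable.from_dichotomous(
        tn=1073 - 63, fp=63, fn=140, tp=156, label="development: dipstick, eGFR>=60"
    )


#: Published screening sensitivities (proportions) by method and subgroup,
#: in the row order of the efficacy table; NNS = 1/sensitivity.
TABLE_SENSITIVITIES: dict[str, float] = {
    "semiq: all": 0.935,
    "semiq: dipstick-negative": 0.833,
    "semiq: eGFR>=60": 0.902,
    "semiq: eGFR>=60, dipstick-negative": 0.813,
    "dipstick: all": 0.656,
    "dipstick: eGFR>=60": 0.527,
}


def illustrative_studies(outcome: str = "death") -> list[StudyEffect]:
    """A small synthetic study set per outcome for exercising the pooling API.

    Values are invented but lie in the range reported across cohort studies of
    albuminuric vs normo-albuminuric diabetic patients (mortality HRs roughly
    1.0–2.2, CVD 1.3–1.9, ESRD 2.7–4.1).  They are NOT the studies of any
    particular published meta-analysis.
    """
    table = {
        "death": [
            ("mortality-A", 1.35, 1.21, 1.51),
            ("mortality-B", 1.62, 1.38, 1.90),
            ("mortality-C", 1.48, 1.40, 1.57),
            ("mortality-D", 1.22, 1.04, 1.43),
            ("mortality-E", 1.79, 1.42, 2.26),
        ],
        "CVD": [
            ("cvd-A", 1.27, 1.16, 1.39),
            ("cvd-B", 1.34, 1.24, 1.45),
            ("cvd-C", 1.52, 1.28, 1.81),
            ("cvd-D", 1.89, 1.44, 2.48),
        ],
        "ESRD": [
            ("esrd-A", 2.71, 2.02, 3.64),
            ("esrd-B", 3.60, 2.62, 4.95),
            ("esrd-C", 4.13, 2.87, 5.94),
        ],
    }
    try:
        rows = table[outcome]
    except KeyError:
        raise ValueError(f"outcome must be one of {sorted(table)}, got {outcome!r}") from None
    return [
        effect_from_ci(hr, lo, hi, study_id=sid, outcome=outcome)
        for sid, hr, lo, hi in rows
    ]
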