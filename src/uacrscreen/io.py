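"""Delimited-text readers and report writers.

All inputs and outputs are plain delimited text (CSV/TSV inferred from the
extension, CSV by default).  Reports mirror the layout of the published
summary tables: concordance counts with row percentages, screening metrics,
forest tables, the two-strategy cost breakdown and the tornado table.
Displayed values are rounded (two decimals for currency, one for
percentages); machine-readable full-precision values are kept in the
DataFrame returns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .accuracy import (
    CATEGORIES,
    AccuracyMetrics,
    ConcordanceTable,
    accuracy_metrics,
    build_concordance,
)
from .econ import COMPONENTS, CostBreakdown, SavedCost, TornadoEntry
from .markov import OUTCOMES, CycleTrace
from .meta import PooledEffect, StudyEffect, effect_from_ci

__all__ = [
    "read_concordance_records",
    "read_concordance_table",
    "read_studies",
    "write_table",
    "accuracy_report",
    "forest_table",
    "cost_report",
    "tornado_table",
]


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_concordance_records(path: str | Path, label: str = "") -> ConcordanceTable:
    """Read per-patient records (columns: id, quantitative_uacr_mg_g, semiquant_category)."""
    df = pd.read_csv(path, sep=_sep(path))
    required = {"quantitative_uacr_mg_g", "semiquant_category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return build_concordance(
        zip(df["quantitative_uacr_mg_g"], df["semiquant_category"]),
        label=label or Path(path).stem,
    )


def read_concordance_table(path: str | Path, label: str = "") -> ConcordanceTable:
    """Read a pre-tabulated 3×3 table: header of semi-quant categories, 3 count rows."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.shape != (3, 3):
        raise ValueError(f"{path}: expected a 3x3 count table, got shape {df.shape}")
    return ConcordanceTable(
        counts=df.to_numpy(dtype=np.int64), label=label or Path(path).stem
    )


def read_studies(path: str | Path) -> list[StudyEffect]:
    """Read a study table (columns: study_id, outcome, hr, ci_low, ci_high)."""
    df = pd.read_csv(path, sep=_sep(path))
    required = {"study_id", "outcome", "hr", "ci_low", "ci_high"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        effect_from_ci(
            float(r.hr), float(r.ci_low), float(r.ci_high),
            study_id=str(r.study_id), outcome=str(r.outcome),
        )
        for r in df.itertuples()
    ]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep(path), index=False, lineterminator="\n")
    return path


def accuracy_report(
    table: ConcordanceTable, metrics: AccuracyMetrics | None = None
) -> pd.DataFrame:
    """Concordance counts with row percentages plus the screening metrics."""
    if metrics is None:
        metrics = accuracy_metrics(table)
    rows = []
    row_totals = table.counts.sum(axis=1)
    for i, cat in enumerate(CATEGORIES):
        for j, semiq in enumerate(CATEGORIES):
            count = int(table.counts[i, j])
            pct = 100.0 * count / row_totals[i] if row_totals[i] else float("nan")
            rows.append(
                dict(section="concordance", quantitative=cat, semiquant=semiq,
                     count=count, row_pct=round(pct, 1), value=np.nan)
            )
    for name, value, scale in (
        ("sensitivity_pct", metrics.sensitivity, 100.0),
        ("specificity_pct", metrics.specificity, 100.0),
        ("over_detected_pct", metrics.over_detected, 100.0),
        ("under_detected_pct", metrics.under_detected, 100.0),
        ("number_needed_to_screen", metrics.nns, 1.0),
    ):
        rows.append(
            dict(section="metrics", quantitative="", semiquant="",
                 count=table.n if name == "sensitivity_pct" else np.nan,
                 row_pct=np.nan, value=round(value * scale, 1))
        )
        rows[-1]["metric"] = name
    df = pd.DataFrame(rows)
    df["label"] = table.label
    return df


def forest_table(
    effects: Sequence[StudyEffect], pooled: Sequence[PooledEffect]
) -> pd.DataFrame:
    """Per-study rows followed by pooled rows, on the hazard-ratio scale."""
    rows = [
        dict(row="study", study_id=e.study_id, outcome=e.outcome, model="",
             hr=e.hr, ci_low=e.ci_low, ci_high=e.ci_high,
             weight_pct=np.nan, tau2=np.nan, i2=np.nan, het_p=np.nan)
        for e in effects
    ]
    for p in pooled:
        rows.append(
            dict(row="pooled", study_id=f"pooled ({p.model})",
                 outcome=effects[0].outcome if effects else "", model=p.model,
                 hr=p.hr, ci_low=p.ci_low, ci_high=p.ci_high,
                 weight_pct=100.0, tau2=p.tau2, i2=p.i2, het_p=p.het_p)
        )
    return pd.DataFrame(rows)


_COMPONENT_LABELS = {
    "screening_test": "Initial screening test",
    "screening_transport": "Screening transportation",
    "confirmatory_test": "Confirmatory quantitative test",
    "confirmatory_transport": "Confirmatory transportation",
    "outcome_ESRD": "Under-detected: end-stage renal disease",
    "outcome_CVD": "Under-detected: cardiovascular disease",
    "outcome_death": "Under-detected: all-cause mortality",
}


def cost_report(
    q: CostBreakdown, semiq: CostBreakdown, saving: SavedCost, currency: str = "USD"
) -> pd.DataFrame:
    """Two-strategy cost table: component rows, crude/discounted sums, saved cost."""
    rows = []
    for key in COMPONENTS:
        rows.append(
            dict(
                row=_COMPONENT_LABELS[key],
                quantitative=round(q.crude[key], 2),
                semi_quantitative=round(semiq.crude[key], 2),
            )
        )
    rows.append(dict(row="Summed costs (crude)",
                     quantitative=round(q.summed_crude, 2),
                     semi_quantitative=round(semiq.summed_crude, 2)))
    rows.append(dict(row="Summed costs (discounted)",
                     quantitative=round(q.summed_discounted, 2),
                     semi_quantitative=round(semiq.summed_discounted, 2)))
    rows.append(dict(row="Saved cost (crude)", quantitative=np.nan,
                     semi_quantitative=round(saving.crude_saving, 2)))
    rows.append(dict(row="Saved cost (crude, %)", quantitative=np.nan,
                     semi_quantitative=round(100.0 * saving.crude_fraction, 1)))
    rows.append(dict(row="Saved cost (discounted)", quantitative=np.nan,
                     semi_quantitative=round(saving.discounted_saving, 2)))
    df = pd.DataFrame(rows)
    df.attrs["currency"] = currency
    return df


def tornado_table(baseline: float, entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    """Tornado entries ordered by span, with the baseline saving attached."""
    rows = [
        dict(
            parameter=e.parameter,
            low_input=e.low_input,
            high_input=e.high_input,
            saving_at_low=round(e.saving_at_low, 2),
            saving_at_high=round(e.saving_at_high, 2),
            span=round(e.span, 2),
            baseline_saving=round(baseline, 2),
        )
        for e in entries
    ]
    return pd.DataFrame(rows)


def trace_table(trace: CycleTrace) -> pd.DataFrame:
    """Long-format per-cycle export of a cohort trace."""
    return trace.to_frame()
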