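"""Concordance tables and diagnostic accuracy of semi-quantitative uACR screening.

The semi-quantitative point-of-care test reports the urine albumin-creatinine
ratio (uACR) in three categories — <30, 30–300 and ≥300 mg/g — while the
laboratory immunoturbidimetric assay gives a continuous value.  Cross-tabulating
the two methods on the same patients yields a 3×3 concordance table, from which
all screening-performance quantities follow after dichotomising both methods at
the albuminuria threshold of 30 mg/g (30 mg/g itself counts as positive).

Besides the usual sensitivity/specificity, two cohort-level fractions are used:
``over_detected`` (false positives / all screened) and ``under_detected``
(false negatives / all screened), and the number needed to screen (NNS),
the expected number of test applications per true case detected, taken as
1/sensitivity.

The module also derives the four per-cycle chance-node proportions that drive
the screening Markov model (:class:`ScreeningParams`), carried as beta
pseudo-counts so their provenance in the concordance table is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CATEGORIES",
    "UndefinedMetricError",
    "BetaProportion",
    "ConcordanceTable",
    "AccuracyMetrics",
    "ScreeningParams",
    "build_concordance",
    "accuracy_metrics",
    "strategy_probabilities",
    "number_needed_to_screen",
]

#: uACR categories in increasing order; bin edges 30 and 300 mg/g belong upward.
CATEGORIES: tuple[str, str, str] = ("<30", "30-300", ">=300")

_BIN_EDGES = (30.0, 300.0)

# accepted spellings for category labels (en-dash, unicode >=, spacing)
_CATEGORY_ALIASES = {
    "<30": 0,
    "< 30": 0,
    "30-300": 1,
    "30–300": 1,
    "30 - 300": 1,
    ">=300": 2,
    "≥300": 2,
    ">= 300": 2,
}


class UndefinedMetricError(ValueError):
    """A requested ratio has a zero denominator (e.g. no quantitative positives)."""


@dataclass(frozen=True)
class BetaProportion:
    """A proportion carried as beta pseudo-counts ``(a, b)``; mean ``a/(a+b)``.

    The counts keep the provenance of each model probability (which cells of
    the concordance table it came from) and support probabilistic sampling;
    the deterministic cohort model uses only :attr:`mean`.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.a + self.b <= 0:
            raise ValueError(f"invalid beta counts ({self.a}, {self.b})")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def n(self) -> float:
        return self.a + self.b


@dataclass(frozen=True)
class ConcordanceTable:
    """3×3 cross-tabulation of quantitative (rows) vs semi-quantitative (columns) uACR category."""

    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 3):
            raise ValueError(f"counts must be 3x3, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("concordance counts must be non-negative")
        if counts.sum() < 1:
            raise ValueError("concordance table must contain at least one record")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_dichotomous(
        cls, tn: int, fp: int, fn: int, tp: int, label: str = ""
    ) -> "ConcordanceTable":
        """Build a table from dichotomised (negative/positive at 30 mg/g) counts.

        Positives are placed in the 30–300 bin; all dichotomised metrics depend
        only on the 2×2 margins, so the split between the two positive bins is
        immaterial.  Used for dipstick-vs-quantitative inputs and for cohorts
        reported only as TN/FP/FN/TP.
        """
        counts = np.zeros((3, 3), dtype=np.int64)
        counts[0, 0], counts[0, 1] = tn, fp
        counts[1, 0], counts[1, 1] = fn, tp
        return cls(counts=counts, label=label)

    # -- dichotomised margins (positive = ≥30 mg/g on either method) --------
    @property
    def true_positive(self) -> int:
        return int(self.counts[1:, 1:].sum())

    @property
    def false_negative(self) -> int:
        return int(self.counts[1:, 0].sum())

    @property
    def false_positive(self) -> int:
        return int(self.counts[0, 1:].sum())

    @property
    def true_negative(self) -> int:
        return int(self.counts[0, 0])


@dataclass(frozen=True)
class AccuracyMetrics:
    """Dichotomised screening performance derived from a :class:`ConcordanceTable`."""

    sensitivity: float
    specificity: float
    over_detected: float
    under_detected: float
    nns: float
    row_concordance: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "over_detected", "under_detected"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.nns < 1.0:
            raise ValueError(f"nns={self.nns} < 1")


@dataclass(frozen=True)
class ScreeningParams:
    """The four chance-node proportions of the screening decision tree.

    ``q_negative``
        fraction negative (<30 mg/g) at quantitative screening;
    ``semiq_negative``
        fraction negative at semi-quantitative screening;
    ``fn_given_semiq_negative``
        fraction of semi-quantitative negatives who are quantitative-positive;
    ``tp_given_semiq_positive``
        fraction of semi-quantitative positives confirmed quantitative-positive.
    """

    q_negative: BetaProportion
    semiq_negative: BetaProportion
    fn_given_semiq_negative: BetaProportion
    tp_given_semiq_positive: BetaProportion

    @classmethod
    def from_proportions(
        cls,
        q_negative: float,
        semiq_negative: float,
        fn_given_semiq_negative: float,
        tp_given_semiq_positive: float,
    ) -> "ScreeningParams":
        """Construct from bare proportions (pseudo-counts ``(p, 1-p)``)."""
        return cls(
            *(BetaProportion(p, 1.0 - p)
              for p in (q_negative, semiq_negative,
                        fn_given_semiq_negative, tp_given_semiq_positive))
        )


def categorize_uacr(value: float) -> int:
    """Bin a quantitative uACR value (mg/g) into category index 0/1/2."""
    if value < 0:
        raise ValueError(f"uACR value must be non-negative, got {value}")
    if value < _BIN_EDGES[0]:
        return 0
    if value < _BIN_EDGES[1]:
        return 1
    return 2


def category_index(label: str) -> int:
    """Resolve a semi-quantitative category label to its index 0/1/2."""
    key = str(label).strip()
    try:
        return _CATEGORY_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown semi-quantitative category {label!r}; "
            f"expected one of {CATEGORIES}"
        ) from None


def build_concordance(
    records: Iterable[tuple[float, str]], label: str = ""
) -> ConcordanceTable:
    """Tabulate per-patient ``(quantitative uACR mg/g, semi-quantitative category)`` pairs.

    Raises
    ------
    ValueError
        for an empty record sequence, a negative quantitative value, or an
        unrecognised category label (the message names the offending record).
    """
    counts = np.zeros((3, 3), dtype=np.int64)
    n = 0
    for i, (quant, semiq) in enumerate(records):
        try:
            row = categorize_uacr(float(quant))
            col = category_index(semiq)
        except ValueError as exc:
            raise ValueError(f"record {i}: {exc}") from None
        counts[row, col] += 1
        n += 1
    if n == 0:
        raise ValueError("no records supplied; concordance table requires n >= 1")
    return ConcordanceTable(counts=counts, label=label)


def accuracy_metrics(table: ConcordanceTable) -> AccuracyMetrics:
    """Dichotomised sensitivity, specificity, over/under-detected fractions and NNS.

    Both methods are dichotomised at ≥30 mg/g.  ``over_detected`` and
    ``under_detected`` are expressed per screened subject (denominator ``n``),
    the convention used for cohort-level screening yield.
    """
    counts = table.counts
    pos_total = counts[1:, :].sum()
    neg_total = counts[0, :].sum()
    if pos_total == 0:
        raise UndefinedMetricError(
            f"table {table.label!r} has no quantitative-positive subjects; "
            "sensitivity (and NNS) undefined"
        )
    if neg_total == 0:
        raise UndefinedMetricError(
            f"table {table.label!r} has no quantitative-negative subjects; "
            "specificity undefined"
        )
    sensitivity = table.true_positive / pos_total
    specificity = table.true_negative / neg_total
    n = table.n
    row_totals = counts.sum(axis=1)
    row_conc = tuple(
        counts[i, i] / row_totals[i] if row_totals[i] else float("nan")
        for i in range(3)
    )
    return AccuracyMetrics(
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        over_detected=float(table.false_positive / n),
        under_detected=float(table.false_negative / n),
        nns=number_needed_to_screen(sensitivity),
        row_concordance=row_conc,
    )


def number_needed_to_screen(sensitivity: float) -> float:
    """Number needed to screen per true case detected: ``1 / sensitivity``."""
    if not 0.0 < sensitivity <= 1.0:
        raise UndefinedMetricError(
            f"NNS undefined for sensitivity {sensitivity} outside (0, 1]"
        )
    return 1.0 / sensitivity


def strategy_probabilities(table: ConcordanceTable) -> ScreeningParams:
    """Derive the Markov-model chance-node proportions from a concordance table.

    Each proportion is returned with its integer beta counts, e.g. the
    quantitative-negative fraction of the development subgroup is carried as
    Beta(917, 193) rather than 0.826.
    """
    counts = table.counts
    n = table.n
    semiq_neg_total = int(counts[:, 0].sum())
    semiq_pos_total = n - semiq_neg_total
    if semiq_neg_total == 0:
        raise UndefinedMetricError(
            "no semi-quantitative negatives: false-negative fraction undefined"
        )
    if semiq_pos_total == 0:
        raise UndefinedMetricError(
            "no semi-quantitative positives: confirmation fraction undefined"
        )
    q_neg_total = int(counts[0, :].sum())
    return ScreeningParams(
        q_negative=BetaProportion(q_neg_total, n - q_neg_total),
        semiq_negative=BetaProportion(semiq_neg_total, semiq_pos_total),
        fn_given_semiq_negative=BetaProportion(
            table.false_negative, semiq_neg_total - table.false_negative
        ),
        tp_given_semiq_positive=BetaProportion(
            table.true_positive, semiq_pos_total - table.true_positive
        ),
    )
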