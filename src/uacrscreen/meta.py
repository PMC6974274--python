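"""Fixed- and random-effects pooling of hazard ratios across studies.

Study effects arrive as a hazard ratio with a confidence interval; the log
hazard ratio and its standard error are recovered by the usual back-transform
``se = (ln ci_high - ln ci_low) / (2 z)``.  Pooling is inverse-variance
weighted on the log scale; the random-effects model uses the
DerSimonian–Laird method-of-moments estimator of the between-study variance
tau², with heterogeneity summarised by Cochran's Q, I² and the chi-square
Q-test p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StudyEffect",
    "PooledEffect",
    "effect_from_ci",
    "pool_fixed",
    "pool_random",
]

META_OUTCOMES = ("ESRD", "CVD", "death")


def _z(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    # e.g. 1.959964 at the 95% level; kept at full precision because rounding
    # to 1.96 shifts back-transformed SEs in the 4th decimal
    return float(stats.norm.ppf(0.5 + level / 2.0))


@dataclass(frozen=True)
class StudyEffect:
    """One study's hazard ratio with its CI and derived log-scale quantities."""

    study_id: str
    outcome: str
    hr: float
    ci_low: float
    ci_high: float
    log_effect: float
    se: float
    level: float = 0.95


@dataclass(frozen=True)
class PooledEffect:
    """Pooled hazard ratio with heterogeneity statistics."""

    hr: float
    ci_low: float
    ci_high: float
    tau2: float
    q_stat: float
    i2: float
    het_p: float
    model: str  # "fixed" | "random"
    k: int


def effect_from_ci(
    hr: float,
    ci_low: float,
    ci_high: float,
    level: float = 0.95,
    study_id: str = "",
    outcome: str = "death",
) -> StudyEffect:
    """Build a :class:`StudyEffect` from a hazard ratio and its CI bounds."""
    if hr <= 0 or ci_low <= 0 or ci_high <= 0:
        raise ValueError(
            f"{study_id or 'study'}: hr and CI bounds must be positive, "
            f"got ({hr}, {ci_low}, {ci_high})"
        )
    if not ci_low <= hr <= ci_high:
        raise ValueError(
            f"{study_id or 'study'}: CI ({ci_low}, {ci_high}) does not bracket hr {hr}"
        )
    z = _z(level)
    return StudyEffect(
        study_id=study_id,
        outcome=outcome,
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        log_effect=math.log(hr),
        se=(math.log(ci_high) - math.log(ci_low)) / (2.0 * z),
        level=level,
    )


def _validate(effects: Sequence[StudyEffect]) -> tuple[np.ndarray, np.ndarray]:
    if len(effects) == 0:
        raise ValueError("cannot pool an empty study set")
    outcomes = {e.outcome for e in effects}
    if len(outcomes) > 1:
        raise ValueError(f"cannot pool mixed outcomes: {sorted(outcomes)}")
    y = np.array([e.log_effect for e in effects])
    se = np.array([e.se for e in effects])
    if len(effects) > 1 and (se <= 0).any():
        bad = [e.study_id for e, s in zip(effects, se) if s <= 0]
        raise ValueError(f"studies with non-positive SE cannot be weighted: {bad}")
    return y, se


def _pooled(y: np.ndarray, var: np.ndarray, model: str, level: float) -> tuple:
    w = 1.0 / var
    mean = float((w * y).sum() / w.sum())
    se_pool = float(math.sqrt(1.0 / w.sum()))
    z = _z(level)
    return mean, se_pool, math.exp(mean), math.exp(mean - z * se_pool), math.exp(mean + z * se_pool)


def _heterogeneity(y: np.ndarray, se: np.ndarray) -> tuple[float, float, float]:
    """Cochran's Q (fixed-effect weights), I² and the Q-test p-value."""
    k = len(y)
    if k == 1:
        return 0.0, 0.0, 1.0
    w = 1.0 / se**2
    mean = (w * y).sum() / w.sum()
    q = float((w * (y - mean) ** 2).sum())
    df = k - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    het_p = float(stats.chi2.sf(q, df))
    return q, i2, het_p


def pool_fixed(effects: Sequence[StudyEffect]) -> PooledEffect:
    """Inverse-variance fixed-effect pooling on the log hazard-ratio scale."""
    y, se = _validate(effects)
    level = effects[0].level
    if len(effects) == 1:
        e = effects[0]
        return PooledEffect(e.hr, e.ci_low, e.ci_high, 0.0, 0.0, 0.0, 1.0, "fixed", 1)
    q, i2, het_p = _heterogeneity(y, se)
    _, _, hr, lo, hi = _pooled(y, se**2, "fixed", level)
    return PooledEffect(hr, lo, hi, 0.0, q, i2, het_p, "fixed", len(effects))


def pool_random(effects: Sequence[StudyEffect]) -> PooledEffect:
    """DerSimonian–Laird random-effects pooling.

    The between-study variance is the method-of-moments estimate
    ``tau² = max(0, (Q - (k-1)) / (Σw - Σw²/Σw))`` with fixed-effect weights
    ``w = 1/se²``; study weights then become ``1/(se² + tau²)``.
    """
    y, se = _validate(effects)
    level = effects[0].level
    if len(effects) == 1:
        e = effects[0]
        return PooledEffect(e.hr, e.ci_low, e.ci_high, 0.0, 0.0, 0.0, 1.0, "random", 1)
    q, i2, het_p = _heterogeneity(y, se)
    w = 1.0 / se**2
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (len(effects) - 1)) / denom) if denom > 0 else 0.0
    _, _, hr, lo, hi = _pooled(y, se**2 + tau2, "random", level)
    return PooledEffect(hr, lo, hi, tau2, q, i2, het_p, "random", len(effects))
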