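"""Synthetic screening cohorts, study sets, and an individual-level micro-simulator.

Three generators with known ground truth, all pure functions of their
parameters and a seed:

* :func:`generate_cohort` draws patients with a true uACR category from a
  3-class prior and an observed semi-quantitative category from a row-
  stochastic confusion matrix — the data-generating process the diagnostic-
  accuracy metrics should recover.
* :func:`generate_meta_studies` draws study log hazard ratios around a true
  value with between-study standard deviation tau — the process DerSimonian–
  Laird pooling should recover.
* :func:`microsimulate` walks individual patients through the same annual
  screening tree as the deterministic cohort model, with Bernoulli draws at
  every chance node and identical cost-accounting conventions, providing the
  Monte-Carlo cross-check of the cohort expectations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from .accuracy import CATEGORIES
from .markov import (
    COSTED_STRATA,
    OUTCOMES,
    QUANTITATIVE,
    SEMI_QUANTITATIVE,
    ModelConfig,
    albuminuric_probability,
    normalize_strategy,
    rate_to_probability,
)
from .meta import StudyEffect, effect_from_ci

__all__ = [
    "SyntheticCohort",
    "default_category_prior",
    "default_confusion_matrix",
    "generate_cohort",
    "generate_meta_studies",
    "microsimulate",
]

# log-uniform draw ranges per true category (mg/g); values are cosmetic — only
# the bin matters downstream — but keep records realistic.  Upper bin capped
# at 3000 mg/g.
_UACR_RANGES = ((3.0, 30.0), (30.0, 300.0), (300.0, 3000.0))


def default_category_prior() -> np.ndarray:
    """True-category prevalence of the development subgroup: 82.6/16.8/0.6%."""
    return np.array([917, 186, 7], dtype=float) / 1110.0


def default_confusion_matrix() -> np.ndarray:
    """Row-stochastic semi-quantitative response matrix of the development subgroup."""
    counts = np.array([[579, 333, 5], [36, 142, 8], [0, 2, 5]], dtype=float)
    return counts / counts.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated screening cohort with its ground-truth generator settings."""

    patients: pd.DataFrame
    seed: int
    category_prior: np.ndarray
    confusion: np.ndarray

    @property
    def records(self) -> list[tuple[float, str]]:
        """(quantitative uACR, semi-quantitative category) pairs for tabulation."""
        return list(
            zip(
                self.patients["quantitative_uacr_mg_g"],
                self.patients["semiquant_category"],
            )
        )


def _check_stochastic(name: str, vec: np.ndarray, axis: int | None = None) -> None:
    if (vec < 0).any():
        raise ValueError(f"{name} has negative entries")
    sums = vec.sum() if axis is None else vec.sum(axis=axis)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError(f"{name} rows must sum to 1, got {sums}")


def generate_cohort(
    n: int,
    category_prior: np.ndarray | None = None,
    confusion: np.ndarray | None = None,
    seed: int = 0,
    egfr_ge60_prob: float = 1.0,
    dipstick_negative_prob: float = 1.0,
) -> SyntheticCohort:
    """Draw a cohort of ``n`` patients with known category prior and test confusion.

    True categories are multinomial from ``category_prior``; the observed
    semi-quantitative category is drawn from the confusion-matrix row of the
    true category; the continuous quantitative uACR is log-uniform within the
    true category's bin.  The eGFR and dipstick flags are independent
    Bernoulli markers (both 1 by default, matching the baseline subgroup).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    prior = default_category_prior() if category_prior is None else np.asarray(category_prior, float)
    conf = default_confusion_matrix() if confusion is None else np.asarray(confusion, float)
    if prior.shape != (3,):
        raise ValueError(f"category_prior must have 3 entries, got shape {prior.shape}")
    if conf.shape != (3, 3):
        raise ValueError(f"confusion must be 3x3, got shape {conf.shape}")
    _check_stochastic("category_prior", prior)
    _check_stochastic("confusion", conf, axis=1)

    rng = np.random.default_rng(seed)
    true_cat = rng.choice(3, size=n, p=prior)
    # observed category: inverse-CDF draw against the confusion row of each patient
    u = rng.random(n)
    cum = conf.cumsum(axis=1)
    obs_cat = (u[:, None] > cum[true_cat]).sum(axis=1)

    lo = np.array([r[0] for r in _UACR_RANGES])
    hi = np.array([r[1] for r in _UACR_RANGES])
    uacr = np.exp(
        rng.uniform(np.log(lo[true_cat]), np.log(hi[true_cat]))
    )

    patients = pd.DataFrame(
        {
            "id": np.arange(n),
            "true_category": [CATEGORIES[c] for c in true_cat],
            "quantitative_uacr_mg_g": uacr,
            "semiquant_category": [CATEGORIES[c] for c in obs_cat],
            "egfr_ge60": rng.random(n) < egfr_ge60_prob,
            "dipstick_negative": rng.random(n) < dipstick_negative_prob,
        }
    )
    return SyntheticCohort(
        patients=patients, seed=seed, category_prior=prior, confusion=conf
    )


def generate_meta_studies(
    k: int,
    true_log_hr: float,
    tau: float,
    se_range: tuple[float, float] = (0.05, 0.30),
    seed: int = 0,
    outcome: str = "death",
    level: float = 0.95,
) -> list[StudyEffect]:
    """Draw ``k`` study effects around a true log hazard ratio.

    Study-specific standard errors are uniform in ``se_range``; observed log
    hazard ratios are Normal with variance ``tau² + se_i²``; the CI is
    back-computed from the study's own se at the given level.
    """
    if k < 1:
        raise ValueError("study count must be >= 1")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    lo, hi = se_range
    if not 0 < lo <= hi:
        raise ValueError(f"se_range must be positive and ordered, got {se_range}")
    rng = np.random.default_rng(seed)
    se = rng.uniform(lo, hi, size=k)
    y = rng.normal(true_log_hr, np.sqrt(tau**2 + se**2))
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    return [
        effect_from_ci(
            float(np.exp(y[i])),
            float(np.exp(y[i] - z * se[i])),
            float(np.exp(y[i] + z * se[i])),
            level=level,
            study_id=f"synthetic-{i:03d}",
            outcome=outcome,
        )
        for i in range(k)
    ]


def microsimulate(
    strategy: str, config: ModelConfig, n: int, seed: int = 0
) -> pd.DataFrame:
    """Simulate ``n`` individual patients through the screening decision tree.

    Every chance node of the cohort model becomes a Bernoulli/categorical
    draw; cost accounting matches the deterministic engine exactly (screen and
    transport cost per screen, confirmatory cost per strip positive, outcome
    unit cost only for events in screen-negative strata, discounting by
    ``(1+d)^-t`` with the first cycle undiscounted).

    Returns one row per patient: exit cycle (or the horizon if never exited),
    exit reason, counts of screens/confirmatory tests, and crude and
    discounted total cost.
    """
    strategy = normalize_strategy(strategy)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    scr = config.screening
    dt = config.cycle_length

    p_norm = np.array([rate_to_probability(o.rate_normo, dt) for o in config.outcomes])
    p_alb = np.array(
        [albuminuric_probability(o.rate_normo, o.hr_albuminuria, dt) for o in config.outcomes]
    )
    unit_cost = np.array([o.unit_cost for o in config.outcomes])
    cum_norm = p_norm.cumsum()
    cum_alb = p_alb.cumsum()

    if strategy == QUANTITATIVE:
        c_screen = config.cost_quant_test
        screen_trips = config.transport_trips_quant
    else:
        c_screen = config.cost_semiq_test
        screen_trips = config.transport_trips_semiq
    c_screen_total = c_screen + screen_trips * config.cost_transport
    c_confirm_total = (
        config.cost_quant_test + config.transport_trips_confirm * config.cost_transport
    )

    active = np.ones(n, dtype=bool)
    exit_cycle = np.full(n, config.horizon)
    exit_reason = np.array(["none"] * n, dtype=object)
    screens = np.zeros(n, dtype=np.int64)
    confirms = np.zeros(n, dtype=np.int64)
    cost_crude = np.zeros(n)
    cost_disc = np.zeros(n)

    def _events(idx: np.ndarray, cum: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Categorical outcome draw; returns (has_event, outcome_index)."""
        u = rng.random(idx.size)
        k = np.searchsorted(cum, u, side="right")
        return k < len(OUTCOMES), k

    for t in range(config.horizon):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        w = (1.0 + config.discount_rate) ** (-t)
        screens[idx] += 1
        cost_crude[idx] += c_screen_total
        cost_disc[idx] += w * c_screen_total

        if strategy == QUANTITATIVE:
            pos = rng.random(idx.size) < (1.0 - scr.q_negative.mean)
            pos_idx = idx[pos]
            active[pos_idx] = False
            exit_cycle[pos_idx] = t
            exit_reason[pos_idx] = "positive_screen"
            # remaining quantitative negatives face normo-albuminuric risks
            strata = [(idx[~pos], cum_norm, True, "")]
        else:
            strip_pos = rng.random(idx.size) < (1.0 - scr.semiq_negative.mean)
            pos_idx = idx[strip_pos]
            confirms[pos_idx] += 1
            cost_crude[pos_idx] += c_confirm_total
            cost_disc[pos_idx] += w * c_confirm_total
            confirmed = rng.random(pos_idx.size) < scr.tp_given_semiq_positive.mean
            tp_idx = pos_idx[confirmed]
            active[tp_idx] = False
            exit_cycle[tp_idx] = t
            exit_reason[tp_idx] = "confirmed_positive"
            fp_idx = pos_idx[~confirmed]

            neg_idx = idx[~strip_pos]
            is_fn = rng.random(neg_idx.size) < scr.fn_given_semiq_negative.mean
            strata = [
                (neg_idx[~is_fn], cum_norm, True, "tn_"),
                (neg_idx[is_fn], cum_alb, True, "fn_"),
                # false-positive events are recorded but never costed
                (fp_idx, cum_norm, False, "fp_"),
            ]

        for s_idx, cum, costed, prefix in strata:
            if s_idx.size == 0:
                continue
            has_event, which = _events(s_idx, cum)
            ev_idx = s_idx[has_event]
            ev_which = which[has_event]
            active[ev_idx] = False
            exit_cycle[ev_idx] = t
            exit_reason[ev_idx] = [prefix + OUTCOMES[k] for k in ev_which]
            if costed:
                cost_crude[ev_idx] += unit_cost[ev_which]
                cost_disc[ev_idx] += w * unit_cost[ev_which]

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "exit_cycle": exit_cycle,
            "exit_reason": exit_reason,
            "screens": screens,
            "confirmatory_tests": confirms,
            "cost_crude": cost_crude,
            "cost_discounted": cost_disc,
        }
    )
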