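"""Deterministic annual-cycle Markov cohort model of two albuminuria screening strategies.

The model follows a cohort of diabetic patients with normal renal function
through annual screening cycles over a fixed horizon (default 10 years):

* **Quantitative strategy** — every occupant receives the laboratory uACR
  test; positives (≥30 mg/g) are assumed albuminuric, proceed to medical care
  and leave the screening pool.  Negatives remain at risk of the three
  clinical outcomes (ESRD, cardiovascular disease, death) at
  normo-albuminuric rates.

* **Semi-quantitative strategy** — every occupant receives the point-of-care
  strip test; strip positives get a confirmatory quantitative test.  Confirmed
  true positives exit to care; confirmed false positives stay in the pool at
  normo-albuminuric risk.  Strip negatives split into true negatives
  (normo-albuminuric risk) and false negatives, whose outcome probabilities
  are inflated by the outcome-specific hazard ratio of albuminuria.

Annual incidence rates are converted to per-cycle probabilities by
``p = 1 - exp(-rate * time)``; the three outcome probabilities are applied
independently and treated as mutually exclusive within a cycle (their sum is
removed from occupancy).  Any event or exit is absorbing.  Survivors re-enter
the Markov node memorylessly: screening results are re-drawn each cycle from
the same proportions, with no persistence of a patient's false-negative
status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .accuracy import BetaProportion, ScreeningParams

__all__ = [
    "OUTCOMES",
    "QUANTITATIVE",
    "SEMI_QUANTITATIVE",
    "STRATA",
    "COSTED_STRATA",
    "OutcomeParams",
    "ModelConfig",
    "CycleTrace",
    "rate_to_probability",
    "albuminuric_probability",
    "run_strategy",
]

OUTCOMES: tuple[str, str, str] = ("ESRD", "CVD", "death")

QUANTITATIVE = "quantitative"
SEMI_QUANTITATIVE = "semi-quantitative"

_STRATEGY_ALIASES = {
    "quantitative": QUANTITATIVE,
    "q": QUANTITATIVE,
    "semi-quantitative": SEMI_QUANTITATIVE,
    "semiquantitative": SEMI_QUANTITATIVE,
    "semiq": SEMI_QUANTITATIVE,
    "sq": SEMI_QUANTITATIVE,
}

#: occupancy strata whose events are tracked, per strategy
STRATA: dict[str, tuple[str, ...]] = {
    QUANTITATIVE: ("quant_negative",),
    SEMI_QUANTITATIVE: ("true_negative", "false_negative", "false_positive"),
}

#: strata whose events carry cost: the screen-negative ("unavoided") strata.
#: Confirmed false positives are known normo-albuminuric, so their events are
#: recorded but not costed by default (see econ.cost_breakdown).
COSTED_STRATA: dict[str, tuple[str, ...]] = {
    QUANTITATIVE: ("quant_negative",),
    SEMI_QUANTITATIVE: ("true_negative", "false_negative"),
}


def normalize_strategy(strategy: str) -> str:
    try:
        return _STRATEGY_ALIASES[str(strategy).strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected "
            f"{QUANTITATIVE!r} or {SEMI_QUANTITATIVE!r}"
        ) from None


def rate_to_probability(rate: float, time: float = 1.0) -> float:
    """Convert an annual event rate to a probability over ``time`` years.

    Uses the constant-hazard relation ``p = 1 - exp(-rate * time)``.
    """
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if time < 0:
        raise ValueError(f"time must be non-negative, got {time}")
    return -math.expm1(-rate * time)


def albuminuric_probability(rate_normo: float, hr: float, time: float = 1.0) -> float:
    """Per-cycle outcome probability in albuminuric patients.

    The normo-albuminuric rate is scaled by the hazard ratio before the
    rate-to-probability conversion: ``1 - exp(-rate * hr * time)``.
    """
    if hr <= 0:
        raise ValueError(f"hazard ratio must be positive, got {hr}")
    return rate_to_probability(rate_normo * hr, time)


@dataclass(frozen=True)
class OutcomeParams:
    """Annual incidence, relative hazard and unit cost for one clinical outcome.

    ``rate_normo`` is the annual incidence (events/person-year) among
    normo-albuminuric diabetic patients; ``hr_albuminuria`` the hazard ratio
    of albuminuric vs normo-albuminuric patients; ``unit_cost`` the one-off
    cost per event (annual treatment cost for ESRD/CVD, willingness-to-pay
    value of a life-year for death).  ``hr_ci`` carries the 95% CI used by
    the one-way sensitivity analysis.
    """

    name: str
    rate_normo: float
    hr_albuminuria: float
    unit_cost: float
    hr_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.name not in OUTCOMES:
            raise ValueError(f"outcome name must be one of {OUTCOMES}, got {self.name!r}")
        if self.rate_normo < 0:
            raise ValueError(f"{self.name}: rate_normo must be >= 0")
        if self.hr_albuminuria <= 0:
            raise ValueError(f"{self.name}: hr_albuminuria must be > 0")
        if self.unit_cost < 0:
            raise ValueError(f"{self.name}: unit_cost must be >= 0")
        if self.hr_ci is not None:
            lo, hi = self.hr_ci
            if not 0 < lo <= self.hr_albuminuria <= hi:
                raise ValueError(
                    f"{self.name}: hr_ci {self.hr_ci} does not bracket hr "
                    f"{self.hr_albuminuria}"
                )


@dataclass(frozen=True)
class ModelConfig:
    """Complete parameterisation of the screening cost model."""

    screening: ScreeningParams
    outcomes: tuple[OutcomeParams, ...]
    cost_quant_test: float = 17.76
    cost_semiq_test: float = 0.86
    cost_transport: float = 9.265
    transport_trips_quant: int = 2
    transport_trips_semiq: int = 1
    transport_trips_confirm: int = 1
    discount_rate: float = 0.03
    horizon: int = 10
    cycle_length: float = 1.0
    currency: str = "USD, 2016 prices, 1 USD = 1,160 KRW"

    def __post_init__(self) -> None:
        if tuple(o.name for o in self.outcomes) != OUTCOMES:
            raise ValueError(f"outcomes must be given in order {OUTCOMES}")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 cycle")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be > 0")
        for name in ("cost_quant_test", "cost_semiq_test", "cost_transport"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("transport_trips_quant", "transport_trips_semiq",
                     "transport_trips_confirm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def outcome(self, name: str) -> OutcomeParams:
        return self.outcomes[OUTCOMES.index(name)]

    # -- one-way sensitivity support ----------------------------------------
    def parameter_names(self) -> tuple[str, ...]:
        """Scalar parameters recognised by :meth:`with_param`."""
        names = ["cost_quant_test", "cost_semiq_test", "cost_transport"]
        for o in OUTCOMES:
            key = o.lower()
            names += [f"cost_{key}", f"rate_{key}", f"hr_{key}"]
        return tuple(names)

    def get_param(self, name: str) -> float:
        if name in ("cost_quant_test", "cost_semiq_test", "cost_transport"):
            return getattr(self, name)
        kind, _, outcome_key = name.partition("_")
        outcome = _outcome_from_key(outcome_key)
        if outcome is not None and kind in ("cost", "rate", "hr"):
            attr = {"cost": "unit_cost", "rate": "rate_normo", "hr": "hr_albuminuria"}[kind]
            return getattr(self.outcome(outcome), attr)
        raise KeyError(
            f"unknown parameter {name!r}; valid names: {', '.join(self.parameter_names())}"
        )

    def with_param(self, name: str, value: float) -> "ModelConfig":
        """Return a copy with one scalar parameter replaced."""
        if name in ("cost_quant_test", "cost_semiq_test", "cost_transport"):
            return replace(self, **{name: value})
        kind, _, outcome_key = name.partition("_")
        outcome = _outcome_from_key(outcome_key)
        if outcome is not None and kind in ("cost", "rate", "hr"):
            attr = {"cost": "unit_cost", "rate": "rate_normo", "hr": "hr_albuminuria"}[kind]
            new_outcomes = []
            for o in self.outcomes:
                if o.name == outcome:
                    kwargs = {attr: value}
                    if kind == "hr":
                        # widen/clear the CI so the invariant still holds
                        kwargs["hr_ci"] = None
                    o = replace(o, **kwargs)
                new_outcomes.append(o)
            return replace(self, outcomes=tuple(new_outcomes))
        raise KeyError(
            f"unknown parameter {name!r}; valid names: {', '.join(self.parameter_names())}"
        )


def _outcome_from_key(key: str) -> str | None:
    for o in OUTCOMES:
        if key.lower() == o.lower():
            return o
    return None


@dataclass(frozen=True)
class CycleTrace:
    """Per-cycle expectations from one strategy run, per person entering the model.

    All arrays have length ``horizon``.  ``events[(outcome, stratum)][t]`` is
    the expected number of events of that outcome in that stratum during cycle
    ``t``.  Mass conservation holds each cycle:
    ``occupancy[t] = exits_to_care[t] + sum(events[.., t]) + survivors[t]``.
    """

    strategy: str
    config: ModelConfig
    occupancy: np.ndarray
    screens: np.ndarray
    confirmatory: np.ndarray
    exits_to_care: np.ndarray
    events: Mapping[tuple[str, str], np.ndarray]
    survivors: np.ndarray

    @property
    def horizon(self) -> int:
        return len(self.occupancy)

    @property
    def total_screens(self) -> float:
        return float(self.screens.sum())

    @property
    def total_confirmatory(self) -> float:
        return float(self.confirmatory.sum())

    def events_per_cycle(self, outcome: str, strata: tuple[str, ...] | None = None) -> np.ndarray:
        """Expected events of one outcome per cycle, summed over ``strata``."""
        if strata is None:
            strata = STRATA[self.strategy]
        total = np.zeros(self.horizon)
        for s in strata:
            total += self.events[(outcome, s)]
        return total

    def to_frame(self):
        """Long-format export: one row per cycle × quantity."""
        import pandas as pd

        rows = []
        for t in range(self.horizon):
            rows.append((t, "occupancy", "", self.occupancy[t]))
            rows.append((t, "screens", "", self.screens[t]))
            rows.append((t, "confirmatory", "", self.confirmatory[t]))
            rows.append((t, "exits_to_care", "", self.exits_to_care[t]))
            for (outcome, stratum), arr in self.events.items():
                rows.append((t, f"events_{outcome}", stratum, arr[t]))
            rows.append((t, "survivors", "", self.survivors[t]))
        return pd.DataFrame(rows, columns=["cycle", "quantity", "stratum", "value"])


def run_strategy(strategy: str, config: ModelConfig) -> CycleTrace:
    """Run the deterministic cohort model for one strategy over the full horizon.

    Within each cycle, in order: (1) every occupant is screened; (2) screening
    positives exit (quantitative) or are confirmed and split into exits and
    retained false positives (semi-quantitative); (3) outcome probabilities
    are applied to the remaining strata; (4) survivors re-enter the next cycle.
    """
    strategy = normalize_strategy(strategy)
    horizon = config.horizon
    dt = config.cycle_length
    scr = config.screening

    p_norm = {o.name: rate_to_probability(o.rate_normo, dt) for o in config.outcomes}
    p_alb = {
        o.name: albuminuric_probability(o.rate_normo, o.hr_albuminuria, dt)
        for o in config.outcomes
    }
    for label, probs in (("normo-albuminuric", p_norm), ("albuminuric", p_alb)):
        total = sum(probs.values())
        if total > 1.0:
            raise ValueError(
                f"combined {label} outcome probability {total:.4f} exceeds 1; "
                "rates/hazard ratios are too large for mutually exclusive events"
            )

    occupancy = np.zeros(horizon)
    screens = np.zeros(horizon)
    confirmatory = np.zeros(horizon)
    exits = np.zeros(horizon)
    survivors = np.zeros(horizon)
    events = {
        (outcome, stratum): np.zeros(horizon)
        for outcome in OUTCOMES
        for stratum in STRATA[strategy]
    }

    occ = 1.0
    for t in range(horizon):
        occupancy[t] = occ
        screens[t] = occ
        if strategy == QUANTITATIVE:
            neg = occ * scr.q_negative.mean
            exits[t] = occ - neg
            strata_mass = {"quant_negative": neg}
        else:
            pos = occ * (1.0 - scr.semiq_negative.mean)
            neg = occ - pos
            confirmatory[t] = pos
            exits[t] = pos * scr.tp_given_semiq_positive.mean
            fn = neg * scr.fn_given_semiq_negative.mean
            strata_mass = {
                "true_negative": neg - fn,
                "false_negative": fn,
                "false_positive": pos - exits[t],
            }
        surv = 0.0
        for stratum, mass in strata_mass.items():
            probs = p_alb if stratum == "false_negative" else p_norm
            for outcome in OUTCOMES:
                events[(outcome, stratum)][t] = mass * probs[outcome]
            surv += mass * (1.0 - sum(probs.values()))
        survivors[t] = surv
        occ = surv

    for arr in (occupancy, screens, confirmatory, exits, survivors, *events.values()):
        arr.setflags(write=False)
    return CycleTrace(
        strategy=strategy,
        config=config,
        occupancy=occupancy,
        screens=screens,
        confirmatory=confirmatory,
        exits_to_care=exits,
        events=events,
        survivors=survivors,
    )
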