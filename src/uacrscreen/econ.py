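"""Cost accounting, cost-saving comparison and one-way (tornado) sensitivity analysis.

Turns a :class:`~uacrscreen.markov.CycleTrace` into a per-person 10-year cost
breakdown: direct medical cost of the screening tests, direct non-medical
transportation cost, confirmatory testing in the semi-quantitative arm, and
the indirect cost of *unavoided* clinical outcomes — events occurring in
patients the screening declared negative.  Events among confirmed false
positives are known normo-albuminuric cases and carry no cost by default.

Costs are reported both crude and discounted at the configured annual rate
(3%/year by default), with the first cycle undiscounted.  The saving of the
semi-quantitative strategy is the difference in strategy totals; one-way
sensitivity re-runs the whole model at the bounds of one parameter at a time
and a tornado analysis orders parameters by the width of the induced saving
range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .markov import (
    COSTED_STRATA,
    OUTCOMES,
    QUANTITATIVE,
    SEMI_QUANTITATIVE,
    CycleTrace,
    ModelConfig,
    run_strategy,
)

__all__ = [
    "CostBreakdown",
    "SavedCost",
    "TornadoEntry",
    "cost_breakdown",
    "saved_cost",
    "strategy_saving",
    "one_way_sensitivity",
    "default_parameter_ranges",
    "tornado",
]

#: component keys in report order
COMPONENTS = (
    "screening_test",
    "screening_transport",
    "confirmatory_test",
    "confirmatory_transport",
    "outcome_ESRD",
    "outcome_CVD",
    "outcome_death",
)


@dataclass(frozen=True)
class CostBreakdown:
    """Per-person cost components of one strategy over the model horizon."""

    strategy: str
    crude: dict[str, float]
    discounted: dict[str, float]
    horizon: int
    discount_rate: float

    @property
    def summed_crude(self) -> float:
        return sum(self.crude.values())

    @property
    def summed_discounted(self) -> float:
        return sum(self.discounted.values())


@dataclass(frozen=True)
class SavedCost:
    """Cost saved by the semi-quantitative strategy relative to the quantitative one."""

    crude_saving: float
    crude_fraction: float
    discounted_saving: float
    discounted_fraction: float


@dataclass(frozen=True)
class TornadoEntry:
    """Saving at the two bounds of one parameter in a one-way sensitivity analysis."""

    parameter: str
    low_input: float
    high_input: float
    saving_at_low: float
    saving_at_high: float

    @property
    def span(self) -> float:
        return abs(self.saving_at_high - self.saving_at_low)


def _discount_weights(horizon: int, rate: float) -> np.ndarray:
    # first cycle undiscounted: weight (1+d)^0 at t = 0
    return (1.0 + rate) ** (-np.arange(horizon, dtype=float))


def cost_breakdown(
    trace: CycleTrace,
    config: ModelConfig | None = None,
    include_false_positive_events: bool = False,
) -> CostBreakdown:
    """Aggregate a cycle trace into crude and discounted cost components.

    Parameters
    ----------
    trace
        Output of :func:`~uacrscreen.markov.run_strategy`.
    config
        Must be the configuration the trace was produced under; defaults to
        ``trace.config``.
    include_false_positive_events
        If True, events among confirmed false positives in the
        semi-quantitative arm are costed like other events.  Off by default:
        these patients are known normo-albuminuric, so their outcomes are not
        attributable to a screening error.
    """
    if config is None:
        config = trace.config
    elif config is not trace.config and config != trace.config:
        raise ValueError(
            f"trace was produced under a different configuration "
            f"(strategy {trace.strategy!r})"
        )
    w = _discount_weights(trace.horizon, config.discount_rate)

    if trace.strategy == QUANTITATIVE:
        c_screen = config.cost_quant_test
        screen_trips = config.transport_trips_quant
    else:
        c_screen = config.cost_semiq_test
        screen_trips = config.transport_trips_semiq

    costed = list(COSTED_STRATA[trace.strategy])
    if include_false_positive_events and trace.strategy == SEMI_QUANTITATIVE:
        costed.append("false_positive")

    flows: dict[str, np.ndarray] = {
        "screening_test": trace.screens * c_screen,
        "screening_transport": trace.screens * screen_trips * config.cost_transport,
        "confirmatory_test": trace.confirmatory * config.cost_quant_test,
        "confirmatory_transport": (
            trace.confirmatory * config.transport_trips_confirm * config.cost_transport
        ),
    }
    for outcome in OUTCOMES:
        per_cycle = trace.events_per_cycle(outcome, tuple(costed))
        flows[f"outcome_{outcome}"] = per_cycle * config.outcome(outcome).unit_cost

    crude = {k: float(v.sum()) for k, v in flows.items()}
    discounted = {k: float((v * w).sum()) for k, v in flows.items()}
    return CostBreakdown(
        strategy=trace.strategy,
        crude=crude,
        discounted=discounted,
        horizon=trace.horizon,
        discount_rate=config.discount_rate,
    )


def saved_cost(q: CostBreakdown, semiq: CostBreakdown) -> SavedCost:
    """Absolute and fractional saving of the semi-quantitative strategy."""
    if q.strategy != QUANTITATIVE or semiq.strategy != SEMI_QUANTITATIVE:
        raise ValueError(
            f"expected (quantitative, semi-quantitative) breakdowns, got "
            f"({q.strategy!r}, {semiq.strategy!r})"
        )
    if q.horizon != semiq.horizon:
        raise ValueError("breakdowns cover different horizons")
    crude = q.summed_crude - semiq.summed_crude
    disc = q.summed_discounted - semiq.summed_discounted
    return SavedCost(
        crude_saving=crude,
        crude_fraction=crude / q.summed_crude if q.summed_crude else 0.0,
        discounted_saving=disc,
        discounted_fraction=(
            disc / q.summed_discounted if q.summed_discounted else 0.0
        ),
    )


def strategy_saving(config: ModelConfig, basis: str = "crude") -> float:
    """Run both strategies under ``config`` and return the saving on one basis."""
    if basis not in ("crude", "discounted"):
        raise ValueError(f"basis must be 'crude' or 'discounted', got {basis!r}")
    q = cost_breakdown(run_strategy(QUANTITATIVE, config))
    sq = cost_breakdown(run_strategy(SEMI_QUANTITATIVE, config))
    saving = saved_cost(q, sq)
    return saving.crude_saving if basis == "crude" else saving.discounted_saving


def one_way_sensitivity(
    config: ModelConfig,
    parameter: str,
    low: float,
    high: float,
    basis: str = "discounted",
) -> TornadoEntry:
    """Saving at the two bounds of one parameter, all else at baseline."""
    try:
        config.get_param(parameter)
    except KeyError as exc:
        raise KeyError(str(exc)) from None
    return TornadoEntry(
        parameter=parameter,
        low_input=low,
        high_input=high,
        saving_at_low=strategy_saving(config.with_param(parameter, low), basis),
        saving_at_high=strategy_saving(config.with_param(parameter, high), basis),
    )


def default_parameter_ranges(
    config: ModelConfig, rel: float = 0.20
) -> list[tuple[str, float, float]]:
    """The standard one-way ranges: costs and rates ±20%, hazard ratios at their 95% CI."""
    ranges: list[tuple[str, float, float]] = []
    for name in config.parameter_names():
        base = config.get_param(name)
        if name.startswith("hr_"):
            outcome = config.outcome(
                {"esrd": "ESRD", "cvd": "CVD", "death": "death"}[name[3:]]
            )
            if outcome.hr_ci is not None:
                ranges.append((name, outcome.hr_ci[0], outcome.hr_ci[1]))
            else:
                ranges.append((name, base * (1 - rel), base * (1 + rel)))
        else:
            ranges.append((name, base * (1 - rel), base * (1 + rel)))
    return ranges


def tornado(
    config: ModelConfig,
    parameter_ranges: Sequence[tuple[str, float, float]] | None = None,
    basis: str = "discounted",
) -> tuple[float, list[TornadoEntry]]:
    """One-way sensitivity over a list of ``(parameter, low, high)`` ranges.

    Returns the baseline saving and the entries sorted by span, widest first.
    """
    if parameter_ranges is None:
        parameter_ranges = default_parameter_ranges(config)
    if not parameter_ranges:
        raise ValueError("parameter_ranges must be non-empty")
    baseline = strategy_saving(config, basis)
    entries = [
        one_way_sensitivity(config, name, low, high, basis)
        for name, low, high in parameter_ranges
    ]
    entries.sort(key=lambda e: e.span, reverse=True)
    return baseline, entries
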