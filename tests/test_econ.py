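"""Cost breakdown, discounting, saved cost and tornado sensitivity analysis."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from uacrscreen import (
    QUANTITATIVE,
    SEMI_QUANTITATIVE,
    cost_breakdown,
    one_way_sensitivity,
    run_strategy,
    saved_cost,
    strategy_saving,
    tornado,
)
from uacrscreen.econ import COMPONENTS, default_parameter_ranges

# published two-strategy cost table (USD per person over 10 years)
PUBLISHED_Q = {
    "screening_test": 80.72,
    "screening_transport": 84.22,
    "confirmatory_test": 0.0,
    "confirmatory_transport": 0.0,
    "outcome_ESRD": 15.34,
    "outcome_CVD": 754.57,
    "outcome_death": 910.11,
}
PUBLISHED_SQ = {
    "screening_test": 4.38,
    "screening_transport": 47.15,
    "confirmatory_test": 40.31,
    "confirmatory_transport": 21.03,
    "outcome_ESRD": 13.16,
    "outcome_CVD": 576.99,
    "outcome_death": 702.52,
}


@pytest.fixture(scope="module")
def breakdowns(dev_config):
    q = cost_breakdown(run_strategy(QUANTITATIVE, dev_config))
    sq = cost_breakdown(run_strategy(SEMI_QUANTITATIVE, dev_config))
    return q, sq


class TestCostBreakdown:
    @pytest.mark.parametrize("component", COMPONENTS)
    def test_quantitative_components_match_published(self, breakdowns, component):
        q, _ = breakdowns
        assert q.crude[component] == pytest.approx(PUBLISHED_Q[component], abs=0.01)

    @pytest.mark.parametrize("component", COMPONENTS)
    def test_semiq_components_match_published(self, breakdowns, component):
        _, sq = breakdowns
        assert sq.crude[component] == pytest.approx(PUBLISHED_SQ[component], abs=0.01)

    def test_summed_totals_match_published(self, breakdowns):
        q, sq = breakdowns
        assert q.summed_crude == pytest.approx(1844.97, abs=0.02)
        assert sq.summed_crude == pytest.approx(1405.54, abs=0.02)
        assert q.summed_discounted == pytest.approx(1701.25, abs=0.02)
        assert sq.summed_discounted == pytest.approx(1286.36, abs=0.02)

    def test_decomposition_identity(self, breakdowns):
        for b in breakdowns:
            assert b.summed_crude == pytest.approx(sum(b.crude.values()), abs=1e-9)
            assert b.summed_discounted == pytest.approx(sum(b.discounted.values()), abs=1e-9)

    def test_discounted_never_exceeds_crude(self, breakdowns):
        for b in breakdowns:
            for key in COMPONENTS:
                assert b.discounted[key] <= b.crude[key] + 1e-12

    def test_zero_discount_reproduces_crude(self, dev_config):
        config = replace(dev_config, discount_rate=0.0)
        b = cost_breakdown(run_strategy(SEMI_QUANTITATIVE, config))
        for key in COMPONENTS:
            assert b.discounted[key] == pytest.approx(b.crude[key], rel=1e-12)

    def test_all_unit_costs_zero(self, dev_config):
        config = dev_config
        for name in ("cost_quant_test", "cost_semiq_test", "cost_transport",
                     "cost_esrd", "cost_cvd", "cost_death"):
            config = config.with_param(name, 0.0)
        b = cost_breakdown(run_strategy(QUANTITATIVE, config))
        assert b.summed_crude == 0.0 and b.summed_discounted == 0.0

    def test_cash_flows_linear_in_unit_costs(self, dev_config):
        """Doubling every unit cost doubles every component."""
        doubled = dev_config
        for name in ("cost_quant_test", "cost_semiq_test", "cost_transport",
                     "cost_esrd", "cost_cvd", "cost_death"):
            doubled = doubled.with_param(name, 2 * dev_config.get_param(name))
        for strategy in (QUANTITATIVE, SEMI_QUANTITATIVE):
            b1 = cost_breakdown(run_strategy(strategy, dev_config))
            b2 = cost_breakdown(run_strategy(strategy, doubled))
            for key in COMPONENTS:
                assert b2.crude[key] == pytest.approx(2 * b1.crude[key], rel=1e-12)

    def test_false_positive_events_costed_only_on_request(self, dev_config):
        trace = run_strategy(SEMI_QUANTITATIVE, dev_config)
        base = cost_breakdown(trace)
        with_fp = cost_breakdown(trace, include_false_positive_events=True)
        for key in ("outcome_ESRD", "outcome_CVD", "outcome_death"):
            assert with_fp.crude[key] > base.crude[key]
        for key in ("screening_test", "confirmatory_test"):
            assert with_fp.crude[key] == base.crude[key]

    def test_config_mismatch_rejected(self, dev_config, val_config):
        trace = run_strategy(QUANTITATIVE, dev_config)
        with pytest.raises(ValueError, match="different configuration"):
            cost_breakdown(trace, val_config)


class TestSavedCost:
    def test_development_saving(self, breakdowns):
        s = saved_cost(*breakdowns)
        assert s.crude_saving == pytest.approx(439.44, abs=0.02)
        assert s.crude_fraction == pytest.approx(0.238, abs=5e-4)
        assert s.discounted_saving == pytest.approx(414.89, abs=0.02)

    def test_validation_saving(self, val_config):
        q = cost_breakdown(run_strategy(QUANTITATIVE, val_config))
        sq = cost_breakdown(run_strategy(SEMI_QUANTITATIVE, val_config))
        s = saved_cost(q, sq)
        assert s.crude_saving == pytest.approx(339.6, abs=0.5)
        assert s.crude_fraction == pytest.approx(0.167, abs=1e-3)

    def test_identical_breakdowns_save_nothing(self, breakdowns):
        q, _ = breakdowns
        sq_clone = replace(q, strategy=SEMI_QUANTITATIVE)
        s = saved_cost(q, sq_clone)
        assert s.crude_saving == 0.0 and s.crude_fraction == 0.0

    def test_argument_order_enforced(self, breakdowns):
        q, sq = breakdowns
        with pytest.raises(ValueError, match="expected"):
            saved_cost(sq, q)

    def test_saving_monotone_in_test_costs(self, dev_config):
        base = strategy_saving(dev_config, "crude")
        dearer_q = dev_config.with_param("cost_quant_test", 20.0)
        cheaper_q = dev_config.with_param("cost_quant_test", 15.0)
        assert strategy_saving(dearer_q, "crude") > base > strategy_saving(cheaper_q, "crude")
        dearer_sq = dev_config.with_param("cost_semiq_test", 2.0)
        assert strategy_saving(dearer_sq, "crude") < base


class TestOneWaySensitivity:
    def test_death_cost_range_matches_published(self, dev_config):
        base = dev_config.get_param("cost_death")
        e = one_way_sensitivity(dev_config, "cost_death", 0.8 * base, 1.2 * base,
                                basis="discounted")
        assert e.saving_at_low == pytest.approx(375.6, abs=0.1)
        assert e.saving_at_high == pytest.approx(454.1, abs=0.1)

    def test_zero_width_interval_returns_baseline(self, dev_config):
        base = dev_config.get_param("cost_transport")
        baseline = strategy_saving(dev_config, "discounted")
        e = one_way_sensitivity(dev_config, "cost_transport", base, base, "discounted")
        assert e.saving_at_low == pytest.approx(baseline, rel=1e-12)
        assert e.span == 0.0

    def test_saving_linear_in_transport_cost(self, dev_config):
        """The two-bound line passes through the baseline at the midpoint."""
        base = dev_config.get_param("cost_transport")
        e = one_way_sensitivity(dev_config, "cost_transport", 0.8 * base, 1.2 * base,
                                basis="discounted")
        midpoint = (e.saving_at_low + e.saving_at_high) / 2
        assert midpoint == pytest.approx(strategy_saving(dev_config, "discounted"), rel=1e-10)

    def test_unknown_parameter_rejected_with_names(self, dev_config):
        with pytest.raises(KeyError, match="valid names.*cost_transport"):
            one_way_sensitivity(dev_config, "bogus", 0, 1)


class TestTornado:
    def test_death_cost_has_widest_span(self, dev_config):
        baseline, entries = tornado(dev_config)
        assert entries[0].parameter == "cost_death"
        assert baseline == pytest.approx(414.89, abs=0.02)
        spans = [e.span for e in entries]
        assert spans == sorted(spans, reverse=True)

    def test_validation_savings_stay_positive(self, val_config):
        """Every one-way range keeps the semi-quantitative strategy cost-saving."""
        baseline, entries = tornado(val_config)
        low = min(min(e.saving_at_low, e.saving_at_high) for e in entries)
        assert low > 0
        assert low == pytest.approx(294.0, abs=0.5)
        widest = entries[0]
        assert widest.parameter == "cost_death"
        assert max(widest.saving_at_low, widest.saving_at_high) == pytest.approx(348.5, abs=0.5)

    def test_single_entry_list(self, dev_config):
        baseline, entries = tornado(
            dev_config, [("cost_transport", 8.0, 10.0)], basis="crude"
        )
        assert len(entries) == 1 and entries[0].parameter == "cost_transport"

    def test_empty_ranges_rejected(self, dev_config):
        with pytest.raises(ValueError, match="non-empty"):
            tornado(dev_config, [])

    def test_hr_ranges_use_confidence_intervals(self, dev_config):
        ranges = dict((r[0], r[1:]) for r in default_parameter_ranges(dev_config))
        assert ranges["hr_esrd"] == (2.757, 4.271)
        assert ranges["cost_transport"] == pytest.approx((9.265 * 0.8, 9.265 * 1.2))
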