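"""Rate-probability conversion and the deterministic screening cohort model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from uacrscreen import (
    OUTCOMES,
    QUANTITATIVE,
    SEMI_QUANTITATIVE,
    ModelConfig,
    ScreeningParams,
    albuminuric_probability,
    rate_to_probability,
    run_strategy,
)
from uacrscreen.config import default_outcomes
from uacrscreen.markov import OutcomeParams


class TestRateToProbability:
    @pytest.mark.parametrize(
        "rate, time, expected",
        [
            (0.0, 1.0, 0.0),
            (math.log(2), 1.0, 0.5),
            (0.0154, 1.0, 0.015282),
            (0.0095, 1.0, 0.009455),
        ],
    )
    def test_constant_hazard_conversion(self, rate, time, expected):
        assert rate_to_probability(rate, time) == pytest.approx(expected, abs=1e-6)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            rate_to_probability(-0.1, 1.0)
        with pytest.raises(ValueError):
            rate_to_probability(0.1, -1.0)

    @given(st.floats(min_value=0.0, max_value=1e-4), st.floats(min_value=0.1, max_value=1.0))
    def test_small_rate_limit(self, rate, time):
        """For rate*time <= 1e-4 the probability differs from rate*time by <= (rate*time)^2/2."""
        x = rate * time
        assert abs(rate_to_probability(rate, time) - x) <= x**2 / 2 + 1e-18

    @given(st.floats(min_value=0.0, max_value=5.0), st.floats(min_value=0.0, max_value=5.0))
    def test_bounded_and_monotone(self, rate, time):
        p = rate_to_probability(rate, time)
        assert 0.0 <= p < 1.0
        assert rate_to_probability(rate + 0.1, time + 0.1) >= p


class TestAlbuminuricProbability:
    @pytest.mark.parametrize(
        "rate, hr, expected",
        [(0.0006, 3.432, 0.0020571), (0.0095, 1.480, 0.013962)],
    )
    def test_hazard_scaled_conversion(self, rate, hr, expected):
        assert albuminuric_probability(rate, hr) == pytest.approx(expected, abs=1e-6)

    @given(st.floats(min_value=0.0, max_value=0.5), st.floats(min_value=0.1, max_value=3.0))
    def test_unit_hazard_ratio_identity(self, rate, time):
        assert albuminuric_probability(rate, 1.0, time) == rate_to_probability(rate, time)

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            albuminuric_probability(0.01, 0.0)


def _screens_oracle(config):
    """Closed-form geometric-series total screens for the quantitative strategy."""
    p_total = sum(
        1 - math.exp(-o.rate_normo * config.cycle_length) for o in config.outcomes
    )
    s = config.screening.q_negative.mean * (1 - p_total)
    return (1 - s**config.horizon) / (1 - s)


class TestRunStrategy:
    def test_quantitative_screens_match_geometric_oracle(self, dev_config):
        trace = run_strategy(QUANTITATIVE, dev_config)
        assert trace.total_screens == pytest.approx(_screens_oracle(dev_config), abs=1e-12)
        assert trace.total_screens == pytest.approx(4.545, abs=1e-3)

    def test_semiq_confirmatory_tests(self, dev_config):
        """Expected confirmatory tests over 10 cycles equal the strip-positive share of screens."""
        trace = run_strategy(SEMI_QUANTITATIVE, dev_config)
        pos = 1 - dev_config.screening.semiq_negative.mean
        assert trace.total_confirmatory == pytest.approx(trace.total_screens * pos, rel=1e-12)
        assert trace.total_confirmatory == pytest.approx(2.270, abs=1e-3)

    def test_single_cycle_closed_form(self, dev_config):
        from dataclasses import replace

        config = replace(dev_config, horizon=1)
        trace = run_strategy(QUANTITATIVE, config)
        assert trace.total_screens == 1.0
        q_neg = config.screening.q_negative.mean
        for outcome in OUTCOMES:
            rate = config.outcome(outcome).rate_normo
            expected = q_neg * (1 - math.exp(-rate))
            assert trace.events_per_cycle(outcome).sum() == pytest.approx(expected, abs=1e-15)

    def test_zero_rates_and_perfect_negatives_keep_cohort_intact(self):
        config = ModelConfig(
            screening=ScreeningParams.from_proportions(1.0, 1.0, 0.0, 1.0),
            outcomes=tuple(
                OutcomeParams(name=o, rate_normo=0.0, hr_albuminuria=1.0, unit_cost=0.0)
                for o in OUTCOMES
            ),
        )
        for strategy in (QUANTITATIVE, SEMI_QUANTITATIVE):
            trace = run_strategy(strategy, config)
            assert np.allclose(trace.occupancy, 1.0)
            assert all(arr.sum() == 0.0 for arr in trace.events.values())

    @pytest.mark.parametrize("strategy", [QUANTITATIVE, SEMI_QUANTITATIVE])
    def test_mass_conservation_each_cycle(self, dev_config, strategy):
        """occupancy = exits + events + survivors, cycle by cycle, to 1e-12."""
        trace = run_strategy(strategy, dev_config)
        events = sum(trace.events.values())
        residual = trace.occupancy - trace.exits_to_care - events - trace.survivors
        assert np.abs(residual).max() < 1e-12
        # survivors feed the next cycle's occupancy
        assert np.allclose(trace.survivors[:-1], trace.occupancy[1:], atol=1e-15)

    @pytest.mark.parametrize("strategy", [QUANTITATIVE, SEMI_QUANTITATIVE])
    def test_occupancy_decreases_geometrically(self, dev_config, strategy):
        trace = run_strategy(strategy, dev_config)
        ratios = trace.occupancy[1:] / trace.occupancy[:-1]
        assert (trace.occupancy[1:] < trace.occupancy[:-1]).all()
        assert np.allclose(ratios, ratios[0], atol=1e-12)  # memoryless => constant ratio

    def test_unit_hazard_ratios_equalize_fn_and_tn_event_rates(self, dev_config):
        """With all HRs at 1, false negatives face the same per-occupant risk as true negatives."""
        config = dev_config
        for name in ("hr_esrd", "hr_cvd", "hr_death"):
            config = config.with_param(name, 1.0)
        trace = run_strategy(SEMI_QUANTITATIVE, config)
        scr = config.screening
        neg = trace.occupancy * scr.semiq_negative.mean
        fn_mass = neg * scr.fn_given_semiq_negative.mean
        tn_mass = neg - fn_mass
        for outcome in OUTCOMES:
            fn_rate = trace.events[(outcome, "false_negative")] / fn_mass
            tn_rate = trace.events[(outcome, "true_negative")] / tn_mass
            assert np.allclose(fn_rate, tn_rate, rtol=1e-12)

    def test_unknown_strategy_rejected(self, dev_config):
        with pytest.raises(ValueError, match="unknown strategy"):
            run_strategy("dipstick", dev_config)

    def test_excessive_rates_rejected(self, dev_config):
        config = dev_config.with_param("rate_cvd", 5.0).with_param("rate_death", 5.0)
        with pytest.raises(ValueError, match="exceeds 1"):
            run_strategy(QUANTITATIVE, config)


class TestModelConfig:
    def test_parameter_surface_round_trip(self, dev_config):
        for name in dev_config.parameter_names():
            base = dev_config.get_param(name)
            bumped = dev_config.with_param(name, base * 1.5 + 0.01)
            assert bumped.get_param(name) == pytest.approx(base * 1.5 + 0.01)
            # original untouched
            assert dev_config.get_param(name) == base

    def test_unknown_parameter_lists_valid_names(self, dev_config):
        with pytest.raises(KeyError, match="cost_quant_test"):
            dev_config.with_param("cost_of_tea", 1.0)

    def test_invalid_construction(self, dev_config):
        from dataclasses import replace

        with pytest.raises(ValueError):
            replace(dev_config, horizon=0)
        with pytest.raises(ValueError):
            replace(dev_config, discount_rate=-0.01)
        with pytest.raises(ValueError):
            replace(dev_config, outcomes=dev_config.outcomes[::-1])
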