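"""Model configuration: baseline defaults, YAML loading and validation.

The configuration file is a flat YAML mapping.  Missing keys fall back to the
baseline inputs of the cost model: test unit costs (quantitative 17.76 USD,
semi-quantitative 0.86 USD, transportation 9.265 USD per trip), annual outcome
incidences among normo-albuminuric diabetic patients (death 0.95%, CVD 1.54%,
ESRD 0.06% per year), pooled hazard ratios of albuminuria (ESRD 3.432,
CVD 1.315, death 1.480), outcome unit costs (ESRD 6,810.38, CVD 13,149.62,
death 25,634.48 USD), a 3%/year discount rate and a 10-year horizon.
Screening proportions may be given either as beta counts ``[a, b]`` or as
bare proportions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .accuracy import BetaProportion, ScreeningParams, strategy_probabilities
from .datasets import development_subgroup_table, validation_subgroup_table
from .markov import OUTCOMES, ModelConfig, OutcomeParams

__all__ = [
    "development_config",
    "validation_config",
    "default_outcomes",
    "load_config",
    "config_to_dict",
    "config_digest",
]

# annual incidence (per person-year), hazard ratio (95% CI), unit cost (USD):
# ESRD is rare but costly per year of dialysis; the death "cost" is the
# willingness-to-pay value of one life-year.
_OUTCOME_DEFAULTS = {
    "ESRD": dict(rate=0.0006, hr=3.432, hr_ci=(2.757, 4.271), cost=6810.38),
    "CVD": dict(rate=0.0154, hr=1.315, hr_ci=(1.250, 1.384), cost=13149.62),
    "death": dict(rate=0.0095, hr=1.480, hr_ci=(1.408, 1.556), cost=25634.48),
}

_SCALAR_DEFAULTS = dict(
    cost_quant_test=17.76,
    cost_semiq_test=0.86,
    cost_transport=9.265,
    transport_trips_quant=2,
    transport_trips_semiq=1,
    transport_trips_confirm=1,
    discount_rate=0.03,
    horizon=10,
    cycle_length=1.0,
    currency="USD, 2016 prices, 1 USD = 1,160 KRW",
)

_SCREENING_KEYS = (
    "q_negative",
    "semiq_negative",
    "fn_given_semiq_negative",
    "tp_given_semiq_positive",
)


def default_outcomes() -> tuple[OutcomeParams, ...]:
    return tuple(
        OutcomeParams(
            name=name,
            rate_normo=d["rate"],
            hr_albuminuria=d["hr"],
            unit_cost=d["cost"],
            hr_ci=d["hr_ci"],
        )
        for name, d in ((o, _OUTCOME_DEFAULTS[o]) for o in OUTCOMES)
    )


def development_config() -> ModelConfig:
    """Baseline configuration: development-subgroup screening proportions."""
    return ModelConfig(
        screening=strategy_probabilities(development_subgroup_table()),
        outcomes=default_outcomes(),
        **_SCALAR_DEFAULTS,
    )


def validation_config() -> ModelConfig:
    """Baseline configuration re-parameterised with the validation subgroup."""
    return ModelConfig(
        screening=strategy_probabilities(validation_subgroup_table()),
        outcomes=default_outcomes(),
        **_SCALAR_DEFAULTS,
    )


def _beta_from_value(key: str, value: Any) -> BetaProportion:
    if isinstance(value, (list, tuple)):
        if len(value) != 2:
            raise ValueError(f"screening.{key}: beta counts must be [a, b], got {value!r}")
        return BetaProportion(float(value[0]), float(value[1]))
    p = float(value)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"screening.{key}: proportion {p} outside [0, 1]")
    return BetaProportion(p, 1.0 - p)


def load_config(path: str | Path | None = None, **overrides: Any) -> ModelConfig:
    """Load a model configuration from flat-key YAML, applying baseline defaults.

    An absent or empty file yields the full development-subgroup baseline.
    Keyword overrides are applied on top of the file contents.  Schema
    violations raise ``ValueError`` naming the offending key.
    """
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ValueError(f"{path}: config must be a mapping, got {type(loaded).__name__}")
        data.update(loaded)
    data.update(overrides)

    screening_raw = data.pop("screening", None)
    if screening_raw is None:
        screening = strategy_probabilities(development_subgroup_table())
    else:
        if not isinstance(screening_raw, Mapping):
            raise ValueError("screening: must be a mapping of the four proportions")
        unknown = set(screening_raw) - set(_SCREENING_KEYS)
        if unknown:
            raise ValueError(f"screening: unknown keys {sorted(unknown)}")
        missing = set(_SCREENING_KEYS) - set(screening_raw)
        if missing:
            raise ValueError(f"screening: missing keys {sorted(missing)}")
        screening = ScreeningParams(
            **{k: _beta_from_value(k, screening_raw[k]) for k in _SCREENING_KEYS}
        )

    outcomes = []
    for name in OUTCOMES:
        d = _OUTCOME_DEFAULTS[name]
        key = name.lower()
        hr_ci = data.pop(f"hr_{key}_ci", d["hr_ci"])
        if hr_ci is not None:
            hr_ci = tuple(float(v) for v in hr_ci)
        try:
            outcomes.append(
                OutcomeParams(
                    name=name,
                    rate_normo=float(data.pop(f"rate_{key}", d["rate"])),
                    hr_albuminuria=float(data.pop(f"hr_{key}", d["hr"])),
                    unit_cost=float(data.pop(f"cost_{key}", d["cost"])),
                    hr_ci=hr_ci,
                )
            )
        except ValueError as exc:
            raise ValueError(f"outcome {name}: {exc}") from None

    scalars = dict(_SCALAR_DEFAULTS)
    for key in list(data):
        if key in scalars:
            scalars[key] = data.pop(key)
    if data:
        raise ValueError(f"unknown configuration keys: {sorted(data)}")
    try:
        return ModelConfig(screening=screening, outcomes=tuple(outcomes), **scalars)
    except ValueError as exc:
        raise ValueError(f"invalid configuration: {exc}") from None


def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    """Flatten a ModelConfig back into the YAML key schema."""
    out: dict[str, Any] = {
        "screening": {
            k: [getattr(config.screening, k).a, getattr(config.screening, k).b]
            for k in _SCREENING_KEYS
        }
    }
    for o in config.outcomes:
        key = o.name.lower()
        out[f"rate_{key}"] = o.rate_normo
        out[f"hr_{key}"] = o.hr_albuminuria
        out[f"cost_{key}"] = o.unit_cost
        if o.hr_ci is not None:
            out[f"hr_{key}_ci"] = list(o.hr_ci)
    for key in _SCALAR_DEFAULTS:
        out[key] = getattr(config, key)
    return out


def config_digest(config: ModelConfig) -> str:
    """Stable SHA-256 digest of the canonical configuration dictionary."""
    payload = json.dumps(config_to_dict(config), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()
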