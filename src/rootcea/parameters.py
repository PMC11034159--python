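"""Model parameters: transition probabilities, costs, settings, validation.

All probabilities are stored as *annual, per-tooth* values. Multi-year
interval probabilities (e.g. from a cohort examined every n years) are
converted to annual ones with :func:`annualize` before they enter the model.

The packaged defaults are the base-case values of the published Chinese
public-healthcare scenario: a 60-year-old subject with 23 teeth followed
for 20 annual cycles, costs in 2023 CNY, a 5% annual discount rate applied
to both costs and effects, and a willingness-to-pay of ¥214 per
root-caries-free tooth year (the price of one direct restoration).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "TransitionProbabilities",
    "EffectModifier",
    "CostTable",
    "ModelSettings",
    "ModelConfig",
    "annualize",
    "compound",
    "effective_caries_prob",
    "load_config",
    "base_case",
    "DEFAULT_ONE_WAY_BOUNDS",
    "ParameterError",
]


class ParameterError(ValueError):
    """A parameter violated its domain constraints."""


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1]; got {value!r}")


@dataclass(frozen=True)
class TransitionProbabilities:
    """Annual per-tooth transition probabilities of the root-caries model.

    Attributes
    ----------
    p_car : float
        Annual probability that an intact tooth develops root caries.
    p_fill : float
        Annual probability that a tooth with active (untreated) root caries
        receives a direct restoration.
    p_endo : float
        Conditional probability that a restoration requires endodontic
        treatment (pulp involvement).
    p_crown : float
        Conditional probability that an endodontically treated tooth
        receives a crown afterwards.
    p_ext : float
        Annual probability that a tooth with active root caries is extracted.
    p_fail : float
        Annual probability that a direct restoration fails and is refilled.
    """

    p_car: float = 0.007
    p_fill: float = 0.096
    p_endo: float = 0.268
    p_crown: float = 0.640
    p_ext: float = 0.088
    p_fail: float = 0.079

    def __post_init__(self) -> None:
        for name in ("p_car", "p_fill", "p_endo", "p_crown", "p_ext", "p_fail"):
            _check_unit(name, getattr(self, name))
        if self.p_fill + self.p_ext > 1.0:
            raise ParameterError(
                "p_fill + p_ext must not exceed 1 (the remainder is the "
                f"probability of staying untreated); got {self.p_fill} + {self.p_ext}"
            )


@dataclass(frozen=True)
class EffectModifier:
    """Strategy effect: risk ratio applied to ``p_car`` under fluoride varnish."""

    rr_fluoride: float = 0.396

    def __post_init__(self) -> None:
        if not self.rr_fluoride > 0:
            raise ParameterError(f"rr_fluoride must be > 0; got {self.rr_fluoride!r}")


#: One-way sensitivity bounds (low, high) for every analysed parameter.
#: Probability bounds are 95% CIs of the base values except the two
#: literature-derived conditional probabilities (min/max of source data);
#: cost bounds are the cheapest/most expensive plausible item combinations,
#: varnish is +/-20% of base; the discount-rate range follows national
#: pharmacoeconomic guidance.
DEFAULT_ONE_WAY_BOUNDS: dict[str, tuple[float, float]] = {
    "rr_fluoride": (0.223, 0.702),
    "p_car": (0.005, 0.008),
    "p_fill": (0.062, 0.130),
    "p_endo": (0.157, 0.690),
    "p_crown": (0.349, 0.757),
    "p_ext": (0.055, 0.121),
    "p_fail": (0.012, 0.146),
    "c_varnish": (6.4, 9.6),
    "c_fill": (96.0, 427.06),
    "c_ext": (61.06, 534.66),
    "c_endo": (358.06, 3164.06),
    "c_crown": (1118.0, 4896.0),
    "discount_rate": (0.0, 0.08),
}


@dataclass(frozen=True)
class CostTable:
    """Unit costs in CNY, with one-way sensitivity bounds.

    ``c_endo`` is the full endodontic episode including its own filling
    items, so the cost of a restoration with pulp involvement is ``c_endo``
    (plus ``c_crown`` if crowned), not ``c_fill + c_endo``.
    """

    c_varnish: float = 8.0
    c_fill: float = 214.0
    c_ext: float = 219.66
    c_endo: float = 1468.06
    c_crown: float = 3204.0
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            k: v for k, v in DEFAULT_ONE_WAY_BOUNDS.items() if k.startswith("c_")
        }
    )

    def __post_init__(self) -> None:
        for name in ("c_varnish", "c_fill", "c_ext", "c_endo", "c_crown"):
            value = getattr(self, name)
            if value < 0:
                raise ParameterError(f"{name} must be >= 0; got {value!r}")
            if name in self.bounds:
                low, high = self.bounds[name]
                if not (low <= value <= high):
                    raise ParameterError(
                        f"{name}={value} outside its (low, high) bounds ({low}, {high})"
                    )


@dataclass(frozen=True)
class ModelSettings:
    """Cohort-level settings: tooth count, horizon, discounting, thresholds."""

    n_teeth: int = 23
    horizon: int = 20
    discount_rate: float = 0.05
    wtp: float = 214.0
    ppp_rate: float = 3.92

    def __post_init__(self) -> None:
        if self.n_teeth < 1:
            raise ParameterError(f"n_teeth must be >= 1; got {self.n_teeth!r}")
        if self.horizon < 1:
            raise ParameterError(f"horizon must be >= 1; got {self.horizon!r}")
        if not (0.0 <= self.discount_rate < 1.0):
            raise ParameterError(
                f"discount_rate must lie in [0, 1); got {self.discount_rate!r}"
            )
        if self.ppp_rate <= 0:
            raise ParameterError(f"ppp_rate must be > 0; got {self.ppp_rate!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Validated bundle of everything a model run needs.

    ``distributions`` carries raw per-parameter distribution overrides for
    probabilistic sensitivity analysis (see :mod:`rootcea.psa`); an empty
    mapping means the packaged base-case specifications.
    """

    probs: TransitionProbabilities = field(default_factory=TransitionProbabilities)
    modifier: EffectModifier = field(default_factory=EffectModifier)
    costs: CostTable = field(default_factory=CostTable)
    settings: ModelSettings = field(default_factory=ModelSettings)
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ONE_WAY_BOUNDS)
    )
    distributions: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)

    def replace(self, **updates: float) -> "ModelConfig":
        """Return a copy with flat parameter fields replaced.

        Keys are the flat names used in config files (``p_car``,
        ``c_fill``, ``discount_rate``, ...); unknown keys raise
        :class:`ParameterError`. Validation re-runs on the copy.
        """
        prob_f = {f.name for f in dataclasses.fields(TransitionProbabilities)}
        cost_f = {"c_varnish", "c_fill", "c_ext", "c_endo", "c_crown"}
        set_f = {f.name for f in dataclasses.fields(ModelSettings)}
        probs, mod, costs, sett = {}, {}, {}, {}
        for key, value in updates.items():
            if key in prob_f:
                probs[key] = value
            elif key == "rr_fluoride":
                mod[key] = value
            elif key in cost_f:
                costs[key] = value
            elif key in set_f:
                sett[key] = value
            else:
                raise ParameterError(f"unknown parameter {key!r}")
        # cost bounds are widened to admit deliberate out-of-bound overrides
        # during sensitivity analysis; the bounds table itself is untouched
        new_costs = self.costs
        if costs:
            merged = {n: getattr(self.costs, n) for n in cost_f} | costs
            wide = {
                k: (min(v[0], merged[k]), max(v[1], merged[k]))
                for k, v in self.costs.bounds.items()
            }
            new_costs = CostTable(**merged, bounds=wide)
        return ModelConfig(
            probs=dataclasses.replace(self.probs, **probs) if probs else self.probs,
            modifier=dataclasses.replace(self.modifier, **mod) if mod else self.modifier,
            costs=new_costs,
            settings=dataclasses.replace(self.settings, **sett) if sett else self.settings,
            bounds=self.bounds,
            distributions=self.distributions,
        )


def annualize(p_interval: float, n: float) -> float:
    """Convert a probability observed over an ``n``-year interval to annual.

    Uses the constant-hazard identity ``p_annual = 1 - (1 - p_interval)**(1/n)``,
    the exact inverse of compounding a constant annual probability over
    ``n`` years when there is a single way to leave the at-risk state.

    Parameters
    ----------
    p_interval : float
        Probability of the transition over the whole interval, in [0, 1].
    n : float
        Interval length in years, >= 1.
    """
    if not (0.0 <= p_interval <= 1.0):
        raise ParameterError(f"p_interval must lie in [0, 1]; got {p_interval!r}")
    if n < 1:
        raise ParameterError(f"interval length must be >= 1 year; got {n!r}")
    return 1.0 - (1.0 - p_interval) ** (1.0 / n)


def compound(p_annual: float, n: float) -> float:
    """Inverse of :func:`annualize`: probability over ``n`` years."""
    if not (0.0 <= p_annual <= 1.0):
        raise ParameterError(f"p_annual must lie in [0, 1]; got {p_annual!r}")
    if n < 1:
        raise ParameterError(f"interval length must be >= 1 year; got {n!r}")
    return 1.0 - (1.0 - p_annual) ** n


def effective_caries_prob(p_car: float, strategy: str, rr: float) -> float:
    """Annual caries-onset probability under a strategy.

    ``control`` leaves ``p_car`` unchanged; ``fluoride`` multiplies it by
    the varnish risk ratio ``rr``. The product must remain a probability.
    """
    _check_unit("p_car", p_car)
    if strategy == "control":
        return p_car
    if strategy == "fluoride":
        p_eff = rr * p_car
        if p_eff > 1.0:
            raise ParameterError(
                f"rr * p_car = {p_eff} exceeds 1; not a valid probability"
            )
        return p_eff
    raise ParameterError(f"unknown strategy {strategy!r}; use 'control' or 'fluoride'")


_FLAT_KEYS = (
    "p_car",
    "p_fill",
    "p_endo",
    "p_crown",
    "p_ext",
    "p_fail",
    "rr_fluoride",
    "c_varnish",
    "c_fill",
    "c_ext",
    "c_endo",
    "c_crown",
    "n_teeth",
    "horizon",
    "discount_rate",
    "wtp",
    "ppp_rate",
)


def base_case() -> ModelConfig:
    """The packaged base-case configuration."""
    return ModelConfig()


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load a flat JSON/YAML config; missing keys fall back to the base case.

    Recognised keys are the flat parameter names (``p_car`` ... ``ppp_rate``),
    optional ``<name>_low`` / ``<name>_high`` one-way bounds, and an optional
    ``distributions`` block mapping parameter names to distribution specs
    for probabilistic sensitivity analysis.
    """
    if path is None:
        return base_case()
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        raw = yaml.safe_load(text) or {}
    else:
        raw = json.loads(text) if text.strip() else {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config root must be a mapping; got {type(raw).__name__}")

    distributions = raw.pop("distributions", {})
    bounds = dict(DEFAULT_ONE_WAY_BOUNDS)
    flat: dict[str, float] = {}
    for key, value in raw.items():
        if key in _FLAT_KEYS:
            flat[key] = value
        elif key.endswith("_low") and key[:-4] in DEFAULT_ONE_WAY_BOUNDS:
            name = key[:-4]
            bounds[name] = (float(value), bounds[name][1])
        elif key.endswith("_high") and key[:-5] in DEFAULT_ONE_WAY_BOUNDS:
            name = key[:-5]
            bounds[name] = (bounds[name][0], float(value))
        else:
            raise ParameterError(f"unknown config key {key!r}")
    for name, (low, high) in bounds.items():
        if low > high:
            raise ParameterError(f"{name} bounds inverted: low {low} > high {high}")

    config = ModelConfig(bounds=bounds, distributions=distributions)
    return config.replace(**flat) if flat else config
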