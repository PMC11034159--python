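"""One-way sensitivity analysis, tornado ordering and threshold search.

Each analysis perturbs exactly one parameter to a bound, re-runs both
strategies with everything else at base case, and recomputes the ICER. The
willingness-to-pay stays fixed at its base value throughout: it is a
policy threshold, not a model input under uncertainty. ``c_fill`` bounds
apply to initial fillings and refills alike (one price for the procedure).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cea import incremental
from .cohort_engine import CycleConventions, DEFAULT_CONVENTIONS, run_cohort
from .parameters import ModelConfig, ParameterError

__all__ = [
    "OneWayResult",
    "ThresholdResult",
    "one_way",
    "tornado",
    "tornado_table",
    "threshold_search",
    "ONE_WAY_PARAMS",
]

#: Parameters eligible for one-way analysis, in no particular order.
ONE_WAY_PARAMS = (
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
    "discount_rate",
)


@dataclass(frozen=True)
class OneWayResult:
    """ICER response to one parameter swept between its bounds.

    ``direction`` is ``"Increase"`` when the ICER rises with the parameter
    and ``"Decrease"`` when it falls.
    """

    param: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float
    direction: str

    @property
    def range_width(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)

    @property
    def icer_range(self) -> tuple[float, float]:
        return (
            min(self.icer_at_low, self.icer_at_high),
            max(self.icer_at_low, self.icer_at_high),
        )


@dataclass(frozen=True)
class ThresholdResult:
    """Parameter value at which the ICER crosses the willingness-to-pay."""

    param: str
    threshold: float
    bracket: tuple[float, float]
    icer_at_threshold: float
    tolerance_achieved: float


def _icer_at(config: ModelConfig, param: str, value: float, conventions: CycleConventions) -> float:
    modified = config.replace(**{param: value})
    ref = run_cohort(modified, "control", conventions, keep_trace=False)
    comp = run_cohort(modified, "fluoride", conventions, keep_trace=False)
    res = incremental(ref, comp, config.settings.wtp)
    if res.icer is None:
        raise ValueError(f"ICER undefined at {param}={value} (zero incremental effect)")
    return res.icer


def one_way(
    param: str,
    low: float,
    high: float,
    config: ModelConfig,
    conventions: CycleConventions = DEFAULT_CONVENTIONS,
) -> OneWayResult:
    """Recompute the ICER with ``param`` at each bound, all else base case."""
    if param not in ONE_WAY_PARAMS:
        raise ParameterError(
            f"unknown one-way parameter {param!r}; expected one of {ONE_WAY_PARAMS}"
        )
    if low > high:
        raise ParameterError(f"{param}: low bound {low} exceeds high bound {high}")
    icer_low = _icer_at(config, param, low, conventions)
    icer_high = _icer_at(config, param, high, conventions)
    direction = "Increase" if icer_high >= icer_low else "Decrease"
    return OneWayResult(param, low, high, icer_low, icer_high, direction)


def tornado(
    config: ModelConfig,
    bounds: dict[str, tuple[float, float]] | None = None,
    conventions: CycleConventions = DEFAULT_CONVENTIONS,
) -> list[OneWayResult]:
    """One-way results for every parameter, sorted by descending impact."""
    bounds = dict(config.bounds) if bounds is None else bounds
    results = [
        one_way(name, lo, hi, config, conventions) for name, (lo, hi) in bounds.items()
    ]
    return sorted(results, key=lambda res: res.range_width, reverse=True)


def tornado_table(results: list[OneWayResult]) -> pd.DataFrame:
    """Tabular tornado view (one row per parameter, ordered by impact)."""
    return pd.DataFrame(
        {
            "parameter": [r.param for r in results],
            "low": [r.low for r in results],
            "high": [r.high for r in results],
            "icer_at_low": [r.icer_at_low for r in results],
            "icer_at_high": [r.icer_at_high for r in results],
            "icer_range_min": [r.icer_range[0] for r in results],
            "icer_range_max": [r.icer_range[1] for r in results],
            "range_width": [r.range_width for r in results],
            "direction": [r.direction for r in results],
        }
    )


def threshold_search(
    param: str,
    wtp: float,
    bracket: tuple[float, float],
    config: ModelConfig,
    tol: float = 0.01,
    conventions: CycleConventions = DEFAULT_CONVENTIONS,
    max_iter: int = 200,
) -> ThresholdResult:
    """Bisect for the parameter value where the ICER equals ``wtp``.

    Requires the ICER to be monotone in ``param`` over ``bracket`` with a
    sign change of ``ICER - wtp`` across it. Stops when the recomputed ICER
    is within ``tol`` CNY of ``wtp`` or the bracket shrinks below 1e-6.
    """
    lo, hi = bracket
    f_lo = _icer_at(config, param, lo, conventions) - wtp
    f_hi = _icer_at(config, param, hi, conventions) - wtp
    if f_lo == 0.0:
        return ThresholdResult(param, lo, bracket, wtp, 0.0)
    if f_hi == 0.0:
        return ThresholdResult(param, hi, bracket, wtp, 0.0)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no crossing: ICER - wtp has the same sign at both ends of {bracket}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _icer_at(config, param, mid, conventions) - wtp
        if abs(f_mid) <= tol or (hi - lo) < 1e-6:
            return ThresholdResult(param, mid, bracket, f_mid + wtp, abs(f_mid))
        if f_lo * f_mid < 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    mid = 0.5 * (lo + hi)
    f_mid = _icer_at(config, param, mid, conventions) - wtp
    return ThresholdResult(param, mid, bracket, f_mid + wtp, abs(f_mid))
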