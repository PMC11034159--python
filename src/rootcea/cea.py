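"""Incremental cost-effectiveness statistics for two strategy outcomes.

The comparison is always ``comparator - reference`` on unrounded totals.
The ICER (incremental cost per root-caries-free tooth year gained) is only
defined when the incremental effect is nonzero; otherwise the result
carries the net monetary benefit and an explicit flag instead. CNY values
convert to USD by purchasing-power parity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort_engine import CEOutcome
from .parameters import ModelConfig

__all__ = ["IncrementalResult", "incremental", "to_usd", "table_report"]


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental comparison of two strategies at a given willingness-to-pay.

    ``dominance`` is one of ``dominant`` (more effective, less costly),
    ``dominated`` (less effective, more costly), ``tradeoff_quadrant_I``
    (more effective, more costly: cost-effectiveness decided by the WTP) or
    ``tradeoff_quadrant_III`` (less effective, less costly).
    """

    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: str
    wtp: float
    nmb: float
    cost_effective: bool


def _dominance(delta_cost: float, delta_effect: float) -> str:
    if delta_effect > 0 and delta_cost < 0:
        return "dominant"
    if delta_effect < 0 and delta_cost > 0:
        return "dominated"
    if delta_effect >= 0:
        return "tradeoff_quadrant_I"
    return "tradeoff_quadrant_III"


def incremental(reference: CEOutcome, comparator: CEOutcome, wtp: float) -> IncrementalResult:
    """Compare ``comparator`` against ``reference`` (deltas = comparator - reference)."""
    delta_cost = float(comparator.total_cost - reference.total_cost)
    delta_effect = float(comparator.total_effect - reference.total_effect)
    icer = delta_cost / delta_effect if delta_effect != 0.0 else None
    dominance = _dominance(delta_cost, delta_effect)
    nmb = wtp * delta_effect - delta_cost
    cost_effective = dominance == "dominant" or (
        dominance == "tradeoff_quadrant_I" and icer is not None and icer <= wtp
    )
    return IncrementalResult(
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        dominance=dominance,
        wtp=wtp,
        nmb=nmb,
        cost_effective=cost_effective,
    )


def to_usd(amount_cny: float, ppp_rate: float) -> float:
    """Convert CNY to USD at the purchasing-power-parity rate (CNY per USD)."""
    if ppp_rate <= 0:
        raise ValueError(f"ppp_rate must be > 0; got {ppp_rate!r}")
    return amount_cny / ppp_rate


def table_report(
    reference: CEOutcome, comparator: CEOutcome, config: ModelConfig
) -> dict:
    """Base-case report: per-strategy cost/effect, deltas, ICER, USD columns."""
    res = incremental(reference, comparator, config.settings.wtp)
    ppp = config.settings.ppp_rate
    return {
        "strategies": {
            out.strategy: {
                "cost_cny": out.total_cost,
                "cost_usd": to_usd(out.total_cost, ppp),
                "effect_tooth_years": out.total_effect,
            }
            for out in (reference, comparator)
        },
        "incremental": {
            "delta_cost_cny": res.delta_cost,
            "delta_cost_usd": to_usd(res.delta_cost, ppp),
            "delta_effect_tooth_years": res.delta_effect,
            "icer_cny_per_tooth_year": res.icer,
            "icer_usd_per_tooth_year": None if res.icer is None else to_usd(res.icer, ppp),
            "dominance": res.dominance,
            "nmb_cny": res.nmb,
            "wtp_cny": res.wtp,
            "cost_effective": res.cost_effective,
            "comparable": res.icer is not None or res.dominance == "dominant",
        },
    }
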