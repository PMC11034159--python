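"""Independent brute-force oracle: exhaustive event-path enumeration.

Enumerates every possible per-tooth event path over a short horizon,
multiplying branch probabilities exactly and summing discounted cost and
effect. Deliberately written from scratch against the model description
(recursive path expansion, no shared code with the cohort engine) so that
agreement with the engine is a genuine two-route check.
"""

from rootcea.cohort_engine import CycleConventions, State
from rootcea.parameters import ModelConfig, effective_caries_prob


def _resolve_active(probs, costs, conventions):
    """Branches for a tooth with active (new or untreated) root caries."""
    p_fill, p_endo, p_crown, p_ext, p_fail = (
        probs.p_fill,
        probs.p_endo,
        probs.p_crown,
        probs.p_ext,
        probs.p_fail,
    )
    branches = [
        (p_fill * (1 - p_endo), State.FILLED, costs.c_fill),
        (p_fill * p_endo * (1 - p_crown), State.FILLED, costs.c_endo),
        (p_fill * p_endo * p_crown, State.CROWNED, costs.c_endo + costs.c_crown),
        (p_ext, State.EXTRACTED, costs.c_ext),
        (1 - p_fill - p_ext, State.UNTREATED_CARIES, 0.0),
    ]
    if conventions.refill_from == "same_cycle":
        expanded = []
        for prob, nxt, cost in branches:
            if nxt is State.FILLED:
                expanded.append((prob * p_fail, nxt, cost + costs.c_fill))
                expanded.append((prob * (1 - p_fail), nxt, cost))
            else:
                expanded.append((prob, nxt, cost))
        branches = expanded
    return branches


def _cycle_branches(state, probs, costs, conventions):
    if state is State.INTACT:
        out = [(1 - probs.p_car, State.INTACT, 0.0)]
        out += [
            (probs.p_car * p, nxt, cost)
            for p, nxt, cost in _resolve_active(probs, costs, conventions)
        ]
        return out
    if state is State.UNTREATED_CARIES:
        return _resolve_active(probs, costs, conventions)
    if state is State.FILLED:
        return [
            (probs.p_fail, State.FILLED, costs.c_fill),
            (1 - probs.p_fail, State.FILLED, 0.0),
        ]
    return [(1.0, state, 0.0)]


def enumerate_expectations(
    config: ModelConfig,
    strategy: str,
    horizon: int,
    conventions: CycleConventions = CycleConventions(),
):
    """Exact per-tooth expected (discounted cost, discounted effect)."""
    import dataclasses

    p_eff = effective_caries_prob(
        config.probs.p_car, strategy, config.modifier.rr_fluoride
    )
    probs = dataclasses.replace(config.probs, p_car=p_eff)
    costs = config.costs
    r = config.settings.discount_rate
    varnish_on = strategy == "fluoride"

    total = {"cost": 0.0, "effect": 0.0}

    def recurse(state, t, path_prob, cost_acc, effect_acc):
        if t > horizon:
            total["cost"] += path_prob * cost_acc
            total["effect"] += path_prob * effect_acc
            return
        varnish = 0.0
        if varnish_on:
            retained = state is not State.EXTRACTED
            if conventions.varnish_base == "all_teeth" or retained:
                varnish = costs.c_varnish * (1 + r) ** -conventions.discount_exponent(
                    t, "varnish"
                )
        df_treat = (1 + r) ** -conventions.discount_exponent(t, "treatment")
        for prob, nxt, cost in _cycle_branches(state, probs, costs, conventions):
            if prob == 0.0:
                continue
            effect = (1 + r) ** -t if nxt is State.INTACT else 0.0
            recurse(
                nxt,
                t + 1,
                path_prob * prob,
                cost_acc + varnish + cost * df_treat,
                effect_acc + effect,
            )

    recurse(State.INTACT, 1, 1.0, 0.0, 0.0)
    return total["cost"], total["effect"]
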