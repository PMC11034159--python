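import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rootcea.cohort_engine import (
    CalibrationError,
    CohortState,
    CycleConventions,
    DEFAULT_CONVENTIONS,
    State,
    calibrate_conventions,
    closed_form_effect,
    run_cohort,
    step,
)
from rootcea.parameters import ModelConfig, TransitionProbabilities


def _state(**occ):
    vec = np.zeros(5)
    for name, value in occ.items():
        vec[State[name]] = value
    return CohortState(vec)


class TestStep:
    def test_no_disease_limit(self, config):
        """With zero onset risk the cohort stays intact and costs nothing."""
        probs = dataclasses.replace(config.probs, p_car=0.0)
        res = step(CohortState.all_intact(), probs, config.costs, t=1)
        assert res.state[State.INTACT] == 1.0
        assert res.cost == 0.0
        assert res.effect == 1.0

    def test_first_cycle_onset_mass(self, config):
        res = step(CohortState.all_intact(), config.probs, config.costs, t=1)
        assert res.events["new_caries"] == pytest.approx(0.007)
        assert res.state[State.INTACT] == pytest.approx(0.993)

    def test_untreated_pool_branch_masses(self, config):
        """Active caries splits into fill/crown/extract/stay per the event tree."""
        res = step(_state(UNTREATED_CARIES=1.0), config.probs, config.costs, t=1)
        assert res.state[State.FILLED] == pytest.approx(0.096 * (1 - 0.268 * 0.640))
        assert res.state[State.CROWNED] == pytest.approx(0.096 * 0.268 * 0.640)
        assert res.state[State.EXTRACTED] == pytest.approx(0.088)
        assert res.state[State.UNTREATED_CARIES] == pytest.approx(1 - 0.096 - 0.088)

    def test_absorbing_states_cost_nothing(self, config):
        for name in ("CROWNED", "EXTRACTED"):
            res = step(_state(**{name: 1.0}), config.probs, config.costs, t=3)
            assert res.state[State[name]] == 1.0
            assert res.cost == 0.0

    def test_invalid_occupancy_rejected(self):
        with pytest.raises(ValueError):
            CohortState(np.array([0.5, 0.5, 0.5, -0.5, 0.0]))
        with pytest.raises(ValueError):
            CohortState(np.array([0.2, 0.2, 0.2, 0.2, 0.1]))


class TestClosedFormEffect:
    @pytest.mark.parametrize(
        "p, r, T, N, expected, tol",
        [
            (0.007, 0.05, 20, 23, 269.46, 0.01),
            (0.002772, 0.05, 20, 23, 279.67, 0.01),
            (0.0, 0.0, 20, 23, 460.0, 1e-12),
        ],
    )
    def test_examples(self, p, r, T, N, expected, tol):
        assert closed_form_effect(p, r, T, N) == pytest.approx(expected, abs=tol)

    @given(
        p=st.floats(min_value=0.0, max_value=0.5),
        r=st.floats(min_value=0.0, max_value=0.2),
        T=st.integers(min_value=1, max_value=30),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_engine_effect_matches_closed_form(self, config, p, r, T):
        cfg = config.replace(p_car=p, discount_rate=r, horizon=T)
        out = run_cohort(cfg, "control", keep_trace=False)
        expected = closed_form_effect(p, r, T, config.settings.n_teeth)
        assert out.total_effect == pytest.approx(expected, abs=1e-9)


def _random_configs(n, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        p_fill, p_ext = rng.uniform(0, 0.5, 2)
        yield ModelConfig().replace(
            p_car=rng.uniform(0, 1),
            p_fill=p_fill,
            p_ext=min(p_ext, 1 - p_fill),
            p_endo=rng.uniform(0, 1),
            p_crown=rng.uniform(0, 1),
            p_fail=rng.uniform(0, 1),
            rr_fluoride=rng.uniform(0.05, 1.0),
            discount_rate=rng.uniform(0, 0.15),
        )


class TestRunCohort:
    def test_occupancy_conservation_and_absorbing_monotonicity(self):
        """Occupancy sums to one every cycle; intact never grows, crowned and
        extracted never shrink, across randomly drawn parameter sets."""
        for cfg in _random_configs(200, seed=42):
            trace = run_cohort(cfg, "fluoride").trace
            occ = trace[[f"occ_{s.name.lower()}" for s in State]].to_numpy()
            np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(np.diff(occ[:, State.INTACT]) <= 1e-15)
            assert np.all(np.diff(occ[:, State.CROWNED]) >= -1e-15)
            assert np.all(np.diff(occ[:, State.EXTRACTED]) >= -1e-15)

    def test_trace_consistency(self, config):
        out = run_cohort(config, "fluoride")
        trace = out.trace
        assert len(trace) == config.settings.horizon
        n = config.settings.n_teeth
        assert out.total_cost == pytest.approx(
            trace["cycle_cost_discounted"].sum() * n, abs=1e-9
        )
        assert out.total_effect == pytest.approx(
            trace["cycle_effect_discounted"].sum() * n, abs=1e-9
        )
        # effect discounting is end-of-cycle by construction
        df = (1 + config.settings.discount_rate) ** -trace["cycle"].to_numpy()
        np.testing.assert_allclose(
            trace["cycle_effect_discounted"], trace["cycle_effect"] * df, atol=1e-15
        )

    def test_fluoride_effect_dominates_when_rr_below_one(self, config):
        ctrl = run_cohort(config, "control", keep_trace=False)
        flu = run_cohort(config, "fluoride", keep_trace=False)
        assert flu.total_effect > ctrl.total_effect
        eq = config.replace(rr_fluoride=1.0)
        assert run_cohort(eq, "fluoride", keep_trace=False).total_effect == pytest.approx(
            run_cohort(eq, "control", keep_trace=False).total_effect, abs=1e-12
        )

    def test_zero_treatment_costs(self, config):
        """Without treatment costs the control arm is free and the fluoride
        arm pays exactly the varnish annuity (no extractions at p_car=0)."""
        cfg = config.replace(
            p_car=0.0, c_fill=0.0, c_ext=0.0, c_endo=0.0, c_crown=0.0
        )
        assert run_cohort(cfg, "control", keep_trace=False).total_cost == 0.0
        s = config.settings
        annuity = sum(
            8.0 * (1 + s.discount_rate) ** -t for t in range(1, s.horizon + 1)
        )
        flu = run_cohort(cfg, "fluoride", keep_trace=False)
        assert flu.total_cost == pytest.approx(annuity * s.n_teeth, abs=1e-9)


class TestCalibration:
    def test_degenerate_grid_returns_candidate(self, config):
        only = CycleConventions(cost_timing="end_of_cycle")
        best, report = calibrate_conventions(
            config, tolerance=1.0, candidates=[only]
        )
        assert best == only
        assert len(report) == 1

    def test_full_grid_selects_shipped_default(self, config):
        best, report = calibrate_conventions(config)
        assert best == DEFAULT_CONVENTIONS
        assert report["max_rel_err"].iloc[0] <= 0.02

    def test_effects_identical_across_candidates(self, config):
        """Cost-timing conventions never touch the effect total."""
        effects = {
            run_cohort(config, "fluoride", conv, keep_trace=False).total_effect
            for conv in (
                DEFAULT_CONVENTIONS,
                CycleConventions(cost_timing="end_of_cycle", refill_from="next_cycle"),
                CycleConventions(
                    cost_timing="start_of_cycle",
                    varnish_timing="start_of_cycle",
                    half_cycle_correction=True,
                ),
            )
        }
        assert len(effects) == 1

    def test_unreachable_targets_raise_with_report(self, config):
        with pytest.raises(CalibrationError) as err:
            calibrate_conventions(config, targets=(1.0, 1.0))
        assert hasattr(err.value, "report")
        assert len(err.value.report) > 1
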