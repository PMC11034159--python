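import numpy as np
import pandas as pd
import pytest

from rootcea.cea import incremental
from rootcea.cohort_engine import run_cohort
from rootcea.parameters import ParameterError
from rootcea.psa import (
    DistributionSpec,
    beta_from_moments,
    ceac,
    default_specs,
    gamma_from_moments,
    run_psa,
)


class TestMomentFits:
    def test_uniform_beta(self):
        a, b = beta_from_moments(0.5, np.sqrt(1 / 12))
        assert (a, b) == pytest.approx((1.0, 1.0))

    def test_risk_ratio_beta_round_trips(self):
        a, b = beta_from_moments(0.396, 0.0396)
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert mean == pytest.approx(0.396)
        assert np.sqrt(var) == pytest.approx(0.0396)

    def test_onset_beta_counts_match_base_value(self):
        spec = DistributionSpec("beta_ab", alpha=79, beta=11655)
        assert spec.expected == pytest.approx(0.007, abs=3e-4)

    def test_invalid_beta_sd_rejected(self):
        with pytest.raises(ParameterError):
            beta_from_moments(0.5, 0.6)

    @pytest.mark.parametrize(
        "mean, sd, shape, scale",
        [(214.0, 214.0, 1.0, 214.0), (1468.06, 1468.06, 1.0, 1468.06), (10.0, 5.0, 4.0, 2.5)],
    )
    def test_gamma_moments(self, mean, sd, shape, scale):
        assert gamma_from_moments(mean, sd) == pytest.approx((shape, scale))

    def test_gamma_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            gamma_from_moments(-1.0, 1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError):
            DistributionSpec("lognormal", mean=1.0, sd=1.0)


class TestSpecs:
    def test_default_specs_cover_all_sampled_parameters(self, config):
        specs = default_specs(config)
        assert set(specs) == {
            "p_car", "p_fill", "p_endo", "p_crown", "p_ext", "p_fail",
            "rr_fluoride", "c_varnish", "c_fill", "c_ext", "c_endo", "c_crown",
        }
        assert all(s.kind != "fixed" for s in specs.values())

    def test_config_override_freezes_varnish(self, config):
        import dataclasses

        frozen = dataclasses.replace(config, distributions={"c_varnish": {"kind": "fixed"}})
        specs = default_specs(frozen)
        assert specs["c_varnish"].kind == "fixed"
        assert specs["c_varnish"].mean == 8.0

    def test_sample_means_converge_to_spec_means(self, config):
        """Distribution plumbing: 10,000 draws per parameter land within
        4 standard errors of the specified mean."""
        rng = np.random.default_rng(2024)
        n = 10_000
        for name, spec in default_specs(config).items():
            draws = spec.sample(rng, n)
            if spec.kind == "beta_ab":
                a, b = spec.alpha, spec.beta
                sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
            else:
                sd = spec.sd
            se = sd / np.sqrt(n)
            assert abs(draws.mean() - spec.expected) < 4 * se, name


def _fixed_specs(config):
    p, c = config.probs, config.costs
    values = {
        "p_car": p.p_car, "p_fill": p.p_fill, "p_endo": p.p_endo,
        "p_crown": p.p_crown, "p_ext": p.p_ext, "p_fail": p.p_fail,
        "rr_fluoride": config.modifier.rr_fluoride,
        "c_varnish": c.c_varnish, "c_fill": c.c_fill, "c_ext": c.c_ext,
        "c_endo": c.c_endo, "c_crown": c.c_crown,
    }
    return {k: DistributionSpec("fixed", mean=v) for k, v in values.items()}


class TestRunPsa:
    def test_reproducible_bit_identical(self, config):
        a = run_psa(config, n_iter=50, seed=11)
        b = run_psa(config, n_iter=50, seed=11)
        pd.testing.assert_frame_equal(a.iterations, b.iterations)
        pd.testing.assert_frame_equal(a.ceac, b.ceac)
        assert a.summary == b.summary

    def test_degenerate_psa_reproduces_base_case(self, config):
        """With every distribution frozen, all iterations equal the
        deterministic base case and the CEAC is a step at the base ICER."""
        result = run_psa(config, n_iter=20, seed=0, specs=_fixed_specs(config))
        base = incremental(
            run_cohort(config, "control", keep_trace=False),
            run_cohort(config, "fluoride", keep_trace=False),
            config.settings.wtp,
        )
        np.testing.assert_allclose(result.iterations["delta_cost"], base.delta_cost)
        np.testing.assert_allclose(result.iterations["delta_effect"], base.delta_effect)
        curve = result.ceac
        below = curve[curve["wtp"] < base.icer]["probability_cost_effective"]
        above = curve[curve["wtp"] > base.icer]["probability_cost_effective"]
        assert (below == 0.0).all() and (above == 1.0).all()

    def test_quadrant_labels_match_delta_signs(self, config):
        result = run_psa(config, n_iter=100, seed=5)
        it = result.iterations
        dominant = (it["delta_effect"] > 0) & (it["delta_cost"] < 0)
        assert (it.loc[dominant, "quadrant"] == "dominant").all()
        tradeoff = (it["delta_effect"] > 0) & (it["delta_cost"] > 0)
        assert (it.loc[tradeoff, "quadrant"] == "tradeoff_quadrant_I").all()

    def test_fixed_costs_put_every_iteration_in_quadrant_one(self, config):
        """With cost uncertainty removed the varnish annuity always exceeds
        the treatment savings, and rr < 1 a.s. makes fluoride more
        effective: every draw is costlier and more effective."""
        specs = default_specs(config)
        fixed_costs = _fixed_specs(config)
        for name in ("c_varnish", "c_fill", "c_ext", "c_endo", "c_crown"):
            specs[name] = fixed_costs[name]
        result = run_psa(config, n_iter=200, seed=8, specs=specs)
        assert (result.iterations["quadrant"] == "tradeoff_quadrant_I").all()

    def test_ceac_monotone_and_limits(self, config):
        result = run_psa(config, n_iter=300, seed=3)
        probs = result.ceac["probability_cost_effective"].to_numpy()
        assert (result.iterations["delta_effect"] > 0).all()
        assert np.all(np.diff(probs) >= 0)
        # at zero WTP only cost-saving draws count: the dominant fraction
        assert probs[0] == pytest.approx(result.fraction_dominant)
        wide = ceac(result, np.array([0.0, 1e9]))
        assert wide["probability_cost_effective"].iloc[-1] == pytest.approx(1.0)

    def test_empty_result_rejected_by_ceac(self, config):
        result = run_psa(config, n_iter=1, seed=0)
        empty = result.iterations.iloc[0:0]
        import dataclasses

        with pytest.raises(ValueError):
            ceac(dataclasses.replace(result, iterations=empty), np.array([214.0]))
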