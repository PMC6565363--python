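"""Subjective-value closed forms, likelihood oracle, fitting and BIC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import socialsv as ssv
from socialsv.choice_models import FitConfig, PROB_FLOOR
from socialsv.errors import (
    IncompleteGridError,
    InsufficientDataError,
    InvalidParameterError,
)
from socialsv.types import (
    ChoiceTrial,
    InterTemporalOption,
    ModelVariant,
    ParamSet,
    RiskyOption,
    variants,
)


class TestSubjectiveValue:
    @pytest.mark.parametrize(
        "amount, delay, k, expected",
        [
            (10, 0, 0.05, 10.0),  # zero delay leaves value undiscounted
            (40, 180, 1 / 180, 20.0),  # k*t = 1 halves value
            (25, 30, 0.02, 15.625),
        ],
    )
    def test_hyperbolic_closed_form(self, amount, delay, k, expected):
        assert ssv.sv_hyperbolic(InterTemporalOption(amount, delay), k) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize(
        "amount, prob, alpha, expected",
        [
            (10, 1.0, 1.0, 10.0),  # certainty + linearity = face value
            (4, 0.5, 0.5, 1.0),
            (40, 0.2, 1.0, 8.0),  # alpha = 1 reduces to expected value
        ],
    )
    def test_prospect_closed_form(self, amount, prob, alpha, expected):
        assert ssv.sv_prospect(RiskyOption(amount, prob), alpha) == pytest.approx(
            expected, abs=1e-12
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            ssv.sv_hyperbolic(InterTemporalOption(10, 5), -0.1)
        with pytest.raises(InvalidParameterError):
            ssv.sv_prospect(RiskyOption(10, 0.5), 0.0)
        with pytest.raises(InvalidParameterError):
            InterTemporalOption(10, -1)
        with pytest.raises(InvalidParameterError):
            RiskyOption(10, 1.2)

    @given(
        amount=st.floats(0.01, 40),
        delay=st.floats(0, 180),
        k=st.floats(1e-4, 1.0),
        dk=st.floats(1e-4, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_hyperbolic_monotonicity(self, amount, delay, k, dk):
        base = ssv.sv_hyperbolic(InterTemporalOption(amount, delay), k)
        steeper = ssv.sv_hyperbolic(InterTemporalOption(amount, delay), k + dk)
        assert steeper <= base
        assert base <= amount


class TestSoftmax:
    def test_symmetry_and_limits(self):
        assert ssv.p_choose_right(7.3, 7.3, 2.0) == 0.5
        assert ssv.p_choose_right(100, -100, 0.0) == 0.5
        assert ssv.p_choose_right(10, 5, 0.5) == pytest.approx(
            1 / (1 + math.exp(-2.5)), rel=1e-12
        )

    def test_numerically_stable_at_extreme_margins(self):
        assert ssv.p_choose_right(1e4, -1e4, 100.0) == 1.0
        assert ssv.p_choose_right(-1e4, 1e4, 100.0) == 0.0

    @given(
        a=st.floats(-50, 50),
        b=st.floats(-50, 50),
        beta=st.floats(0, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_complementarity(self, a, b, beta):
        p = ssv.p_choose_right(a, b, beta)
        q = ssv.p_choose_right(b, a, beta)
        assert 0.0 <= p <= 1.0
        assert p + q == pytest.approx(1.0, abs=1e-12)

    def test_negative_beta_rejected(self):
        with pytest.raises(InvalidParameterError):
            ssv.p_choose_right(1, 0, -0.5)


def _brute_force_negll(trials, params):
    """Independent oracle: per-trial softmax probabilities via direct exp."""
    total = 1.0
    for t in trials:
        v = params.value_for(t.agent)
        beta = params.noise_for(t.agent)
        if isinstance(t.left, InterTemporalOption):
            sv = lambda o: o.amount / (1 + v * o.delay)
        else:
            sv = lambda o: o.probability * o.amount**v
        er, el = math.exp(beta * sv(t.right)), math.exp(beta * sv(t.left))
        p_right = er / (er + el)
        total *= p_right if t.chosen_side == "right" else 1 - p_right
    return -math.log(total)


class TestLikelihood:
    def test_equal_sv_single_trial_is_ln2(self):
        t = ChoiceTrial(0, "self", InterTemporalOption(10, 0), InterTemporalOption(10, 0), "left")
        params = ParamSet.shared("hyperbolic", 0.05, 1.0)
        assert ssv.neg_log_likelihood([t], params) == pytest.approx(math.log(2))

    def test_zero_beta_gives_n_ln2(self, toy_it_trials):
        params = ParamSet.shared("hyperbolic", 0.05, 0.0)
        assert ssv.neg_log_likelihood(toy_it_trials, params) == pytest.approx(
            5 * math.log(2), abs=1e-12
        )

    @pytest.mark.parametrize("family", ["hyperbolic", "prospect"])
    def test_matches_brute_force_oracle(
        self, family, toy_it_trials, toy_risky_trials
    ):
        trials = toy_it_trials if family == "hyperbolic" else toy_risky_trials
        value = 0.04 if family == "hyperbolic" else 0.8
        for params in (
            ParamSet.shared(family, value, 0.3),
            ParamSet.distinct(family, value, value * 1.3, 0.5, 0.2),
        ):
            assert ssv.neg_log_likelihood(trials, params) == pytest.approx(
                _brute_force_negll(trials, params), rel=1e-10
            )

    def test_dummy_and_error_trials_excluded(self, toy_it_trials):
        params = ParamSet.shared("hyperbolic", 0.05, 0.0)
        import dataclasses

        extra = [
            dataclasses.replace(toy_it_trials[0], trial_id=10, is_dummy=True),
            dataclasses.replace(toy_it_trials[1], trial_id=11, is_error=True,
                                chosen_side="none"),
        ]
        assert ssv.neg_log_likelihood(toy_it_trials + extra, params) == pytest.approx(
            5 * math.log(2)
        )

    def test_empty_usable_raises(self):
        t = ChoiceTrial(0, "self", InterTemporalOption(10, 0), InterTemporalOption(9, 1),
                        "none", is_dummy=True)
        with pytest.raises(InsufficientDataError):
            ssv.neg_log_likelihood([t], ParamSet.shared("hyperbolic", 0.05, 1.0))

    def test_separation_is_finite_via_probability_floor(self):
        # an option pair chosen "wrongly" at enormous beta hits the floor
        t = ChoiceTrial(0, "self", InterTemporalOption(40, 0), InterTemporalOption(1, 180), "right")
        params = ParamSet.shared("hyperbolic", 0.05, 1000.0)
        nll = ssv.neg_log_likelihood([t], params)
        assert math.isfinite(nll)
        assert nll == pytest.approx(-math.log(PROB_FLOOR), rel=1e-6)


class TestBICAndBayesFactor:
    def test_identities(self):
        assert ssv.bic(0, 2, 1) == 0.0
        assert ssv.bic(100, 2, 240) == pytest.approx(2 * math.log(240) + 200)
        # one extra free parameter at unchanged likelihood costs ln n
        assert ssv.bic(50, 3, 240) - ssv.bic(50, 2, 240) == pytest.approx(math.log(240))

    def test_bayes_factor(self):
        assert ssv.approx_bayes_factor(123.4, 123.4) == 1.0
        assert ssv.approx_bayes_factor(2 * math.log(10), 0.0) == pytest.approx(10.0)
        assert ssv.approx_bayes_factor(105, 101) == pytest.approx(math.exp(2))


class TestFitting:
    def test_recovers_shared_k(self, distinct_hyp_params):
        trials = ssv.generate_intertemporal_trialset(0.05, 0.005, rng=11)
        _, placed = ssv.assemble_session(trials, rng=11)
        chosen = ssv.simulate_choices(ParamSet.shared("hyperbolic", 0.02, 0.3), placed, 11)
        fit = ssv.fit_model(chosen, ModelVariant("hyperbolic", 1, 1), FitConfig(seed=1))
        assert fit.converged
        assert abs(math.log10(fit.params.value_self) - math.log10(0.02)) < 0.3

    def test_distinct_k_ordering_recovered(self, distinct_hyp_params):
        trials = ssv.generate_intertemporal_trialset(0.05, 0.005, rng=12)
        _, placed = ssv.assemble_session(trials, rng=12)
        chosen = ssv.simulate_choices(distinct_hyp_params, placed, 12)
        fit = ssv.fit_model(chosen, ModelVariant("hyperbolic", 2, 1),
                            FitConfig(n_restarts=5, seed=2))
        assert fit.params.value_self > fit.params.value_other

    def test_perfect_separation_is_bounded_and_converges(self):
        # dominant option always chosen: the likelihood decreases in beta
        # until every choice is deterministic to machine precision, so the
        # fit lands on that plateau (inside the bounded search region) with
        # an essentially perfect likelihood instead of diverging
        mk = InterTemporalOption
        trials = [
            ChoiceTrial(i, "self", mk(5 + i, 30), mk(20 + i, 1), "right")
            for i in range(40)
        ]
        fit = ssv.fit_model(trials, ModelVariant("hyperbolic", 1, 1),
                            FitConfig(n_restarts=4, seed=3))
        assert fit.converged
        assert fit.params.noise_self <= 1000.0
        assert fit.neg_log_likelihood == pytest.approx(0.0, abs=1e-6)

    def test_bic_consistency_and_free_params(self, toy_it_trials):
        fit = ssv.fit_model(toy_it_trials, ModelVariant("hyperbolic", 1, 1),
                            FitConfig(n_restarts=2, seed=0))
        assert fit.n_free_params == 2
        assert fit.bic == pytest.approx(
            2 * math.log(fit.n_trials_used) + 2 * fit.neg_log_likelihood
        )

    def test_missing_agent_condition_raises(self):
        mk = InterTemporalOption
        self_only = [
            ChoiceTrial(i, "self", mk(5, 30), mk(20, 1), "right") for i in range(10)
        ]
        with pytest.raises(InsufficientDataError):
            ssv.fit_model(self_only, ModelVariant("hyperbolic", 2, 1))


class TestSelection:
    def test_variant_grid(self):
        grid = variants("hyperbolic")
        assert len(grid) == 4
        assert {v.n_free_params for v in grid} == {2, 3, 4}

    def test_tie_breaks_toward_fewer_params(self):
        # n = 1 makes ln(n) = 0, so identical likelihoods tie exactly
        fits = {}
        for v in variants("hyperbolic"):
            params = ParamSet(v, 0.05, 0.05, 0.3, 0.3)
            fits[v] = ssv.FitResult(params, 10.0, 1, v.n_free_params,
                                    ssv.bic(10.0, v.n_free_params, 1), True, 1)
        sel = ssv.select_model({"s0": fits})
        assert sel.winner == ModelVariant("hyperbolic", 1, 1)

    def test_incomplete_grid_raises(self):
        v = ModelVariant("hyperbolic", 1, 1)
        params = ParamSet(v, 0.05, 0.05, 0.3, 0.3)
        fit = ssv.FitResult(params, 10.0, 100, 2, ssv.bic(10.0, 2, 100), True, 1)
        with pytest.raises(IncompleteGridError):
            ssv.select_model({"s0": {v: fit}})
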