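"""Belief state updates, the ten policies, beta superiority and the noise mixture."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from physarum_bandit import (
    DETERMINISTIC_MODELS,
    MODEL_IDS,
    BeliefState,
    PolicySpec,
    apply_noise,
    base_prob,
    beta_superiority,
    init_state,
    initialize_on_arena,
    make_treatment,
    update_state,
)

from _oracles import mc_beta_superiority


def random_state(rng, max_count=6):
    a_r, a_l, b_r, b_l = rng.integers(1, max_count + 1, size=4)
    return BeliefState(
        a_r=float(a_r),
        a_l=float(a_l),
        b_r=float(b_r),
        b_l=float(b_l),
        pos_r=int(a_r + b_r - 2),
        pos_l=int(a_l + b_l - 2),
        last_move=rng.choice([None, "left", "right"]),
    )


class TestStateLifecycle:
    def test_fresh_state_is_uniform_prior(self):
        s = init_state()
        assert (s.a_r, s.a_l, s.b_r, s.b_l) == (1, 1, 1, 1)
        assert s.a_r / (s.a_r + s.b_r) == 0.5  # posterior mean under Beta(1,1)
        assert s.a_r + s.b_r - 2 == 0  # no sites discovered yet
        assert s.last_move is None and s.pos_r == s.pos_l == 0

    def test_arena_initialization_consumes_both_first_sites(self):
        t = make_treatment("4e_vs_8e")
        s = initialize_on_arena(init_state(), t)
        assert (s.a_r, s.a_l, s.b_r, s.b_l) == (2, 2, 1, 1)
        assert s.pos_r == s.pos_l == 1
        assert s.last_move is None
        # symmetry right after initialization
        assert base_prob(PolicySpec("relative_successes"), s) == 0.5

    def test_initialization_requires_fresh_state(self):
        t = make_treatment("4e_vs_8e")
        s = initialize_on_arena(init_state(), t)
        with pytest.raises(ValueError):
            initialize_on_arena(s, t)

    def test_update_increments_only_moved_arm(self):
        s = initialize_on_arena(init_state(), make_treatment("4e_vs_8e"))
        s1 = update_state(s, "right", True)
        assert (s1.a_r, s1.b_r, s1.pos_r) == (s.a_r + 1, s.b_r, s.pos_r + 1)
        assert (s1.a_l, s1.b_l, s1.pos_l) == (s.a_l, s.b_l, s.pos_l)
        assert s1.last_move == "right" and s1.last_rewarded is True
        s2 = update_state(s1, "left", False)
        assert (s2.b_l, s2.a_l) == (s1.b_l + 1, s1.a_l)
        assert s2.last_rewarded is False

    def test_count_conservation_over_updates(self):
        rng = np.random.default_rng(0)
        s = initialize_on_arena(init_state(), make_treatment("4e_vs_8e"))
        for k in range(1, 20):
            s = update_state(s, rng.choice(["left", "right"]), bool(rng.integers(2)))
            assert s.a_r + s.b_r + s.a_l + s.b_l == 4 + 2 + k

    def test_bounds_error_past_arm_end(self):
        s = BeliefState(pos_r=31, pos_l=5, a_r=2, a_l=2)
        with pytest.raises(ValueError):
            update_state(s, "right", True, arm_length=31)

    def test_counts_below_pseudo_observation_rejected(self):
        with pytest.raises(ValueError):
            BeliefState(a_r=0.5)


class TestBetaSuperiority:
    def test_symmetric_state_is_exactly_half(self):
        assert beta_superiority(1, 1, 1, 1) == 0.5
        assert beta_superiority(4, 2, 4, 2) == 0.5

    def test_known_closed_form_value(self):
        # double integral of Beta(2,1) vs Beta(1,2): P(X_R > X_L) = 5/6
        assert beta_superiority(2, 1, 1, 2) == pytest.approx(5 / 6, abs=1e-12)

    def test_monotone_in_successes(self):
        values = [beta_superiority(k, 1, 1, 1) for k in range(1, 8)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_arm_swap_is_exact_complement(self, rng):
        for _ in range(30):
            a_r, b_r, a_l, b_l = rng.integers(1, 10, size=4)
            p = beta_superiority(a_r, b_r, a_l, b_l)
            assert p + beta_superiority(a_l, b_l, a_r, b_r) == 1.0

    def test_non_integer_counts_use_quadrature(self, rng):
        # graded updates produce fractional counts; quadrature must agree with MC
        p = beta_superiority(2.5, 1.0, 1.0, 2.0)
        mc = mc_beta_superiority(2.5, 1.0, 1.0, 2.0, 400_000, rng)
        assert p == pytest.approx(mc, abs=3e-3)

    def test_agrees_with_monte_carlo(self, rng):
        for _ in range(10):
            a_r, b_r, a_l, b_l = rng.integers(1, 12, size=4)
            exact = beta_superiority(a_r, b_r, a_l, b_l)
            mc = mc_beta_superiority(a_r, b_r, a_l, b_l, 200_000, rng)
            assert exact == pytest.approx(mc, abs=4e-3)

    def test_non_positive_counts_rejected(self):
        with pytest.raises(ValueError):
            beta_superiority(0, 1, 1, 1)


class TestModelFormulas:
    def test_relative_successes_is_success_share(self):
        s = BeliefState(a_r=3, a_l=1)
        assert base_prob(PolicySpec("relative_successes"), s) == 0.75

    def test_most_successes_tie_gives_half(self):
        s = BeliefState(a_r=2, a_l=2, b_r=1, b_l=3)
        assert base_prob(PolicySpec("most_successes"), s) == 0.5

    def test_highest_mean_indicator(self):
        s = BeliefState(a_r=2, b_r=1, a_l=1, b_l=2)
        assert base_prob(PolicySpec("highest_mean"), s) == 1.0

    def test_probability_matching_equals_beta_superiority(self):
        s = BeliefState(a_r=2, b_r=1, a_l=1, b_l=2)
        assert base_prob(PolicySpec("probability_matching"), s) == pytest.approx(5 / 6)

    def test_relative_means_symmetric_state(self):
        s = BeliefState(a_r=2, b_r=3, a_l=2, b_l=3)
        assert base_prob(PolicySpec("relative_means"), s) == 0.5

    def test_relative_means_ratio(self):
        s = BeliefState(a_r=2, b_r=1, a_l=1, b_l=2)  # means 2/3 vs 1/3
        assert base_prob(PolicySpec("relative_means"), s) == pytest.approx(2 / 3)

    def test_most_likely_consistent_with_beta_superiority(self, rng):
        spec = PolicySpec("most_likely")
        for _ in range(50):
            s = random_state(rng)
            q = beta_superiority(s.a_r, s.b_r, s.a_l, s.b_l)
            expected = 1.0 if q > 0.5 else (0.0 if q < 0.5 else 0.5)
            assert base_prob(spec, s) == expected

    def test_history_models_default_half_without_history(self):
        s = init_state()
        assert base_prob(PolicySpec("autocorrelation"), s) == 0.5
        assert base_prob(PolicySpec("anti_autocorrelation"), s) == 0.5

    def test_history_models_follow_or_oppose_last_move(self):
        s = BeliefState(last_move="right")
        assert base_prob(PolicySpec("autocorrelation"), s) == 1.0
        assert base_prob(PolicySpec("anti_autocorrelation"), s) == 0.0

    def test_chemotaxis_reads_food_indicators(self):
        s = init_state()
        spec = PolicySpec("chemotaxis")
        assert base_prob(spec, s, food_next_r=True, food_next_l=False) == 1.0
        assert base_prob(spec, s, food_next_r=False, food_next_l=True) == 0.0
        assert base_prob(spec, s, food_next_r=True, food_next_l=True) == 0.5
        assert base_prob(spec, s, food_next_r=False, food_next_l=False) == 0.5

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            PolicySpec("bayes_optimal_oracle")


class TestNoise:
    @pytest.mark.parametrize(
        "p,theta,expected", [(1.0, 0.0, 1.0), (1.0, 1.0, 0.5), (0.75, 0.2, 0.7)]
    )
    def test_mixture_arithmetic(self, p, theta, expected):
        assert apply_noise(p, theta) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_mixture_bounds(self, p, theta):
        out = apply_noise(p, theta)
        assert theta / 2 - 1e-12 <= out <= 1 - theta / 2 + 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_noise(1.2, 0.1)
        with pytest.raises(ValueError):
            apply_noise(0.5, -0.1)


@st.composite
def belief_states(draw):
    counts = draw(st.tuples(*[st.integers(1, 8)] * 4))
    last = draw(st.sampled_from([None, "left", "right"]))
    a_r, a_l, b_r, b_l = counts
    return BeliefState(
        a_r=a_r, a_l=a_l, b_r=b_r, b_l=b_l,
        pos_r=a_r + b_r - 2, pos_l=a_l + b_l - 2, last_move=last,
    )


class TestPolicyAlgebra:
    @pytest.mark.parametrize("model_id", MODEL_IDS)
    @given(state=belief_states(), food=st.tuples(st.booleans(), st.booleans()))
    @settings(max_examples=40, deadline=None)
    def test_normalization_and_mirror_symmetry(self, model_id, state, food):
        spec = PolicySpec(model_id)
        p = base_prob(spec, state, *food)
        assert 0.0 <= p <= 1.0
        mirrored = base_prob(spec, state.mirrored(), food[1], food[0])
        assert mirrored == pytest.approx(1.0 - p, abs=1e-9)

    @pytest.mark.parametrize("model_id", DETERMINISTIC_MODELS)
    @given(state=belief_states(), food=st.tuples(st.booleans(), st.booleans()))
    @settings(max_examples=40, deadline=None)
    def test_deterministic_models_output_indicator_values(self, model_id, state, food):
        assert base_prob(PolicySpec(model_id), state, *food) in (0.0, 0.5, 1.0)

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_symmetric_state_gives_half(self, model_id):
        s = BeliefState(a_r=3, a_l=3, b_r=2, b_l=2, pos_r=3, pos_l=3)
        assert base_prob(PolicySpec(model_id), s) == 0.5
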