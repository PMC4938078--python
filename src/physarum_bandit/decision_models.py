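"""Behavioural decision models for two-armed exploration.

Each model is a stochastic policy returning the probability that the next
move extends the *right* arm, conditioned on a :class:`BeliefState` that
tracks reward/non-reward encounter counts per arm (each with one
pseudo-observation, the Beta(1, 1) uniform prior on food density), the
previous move, and the leading-edge positions. P(left) = 1 - P(right)
always: the agent extends exactly one arm per step.

The model set spans reactive heuristics (follow/oppose the previous move,
chemotaxis to adjacent food), count comparisons (most successes, highest
posterior mean), proportional rules (relative successes, relative means),
fully Bayesian rules built on the posterior probability that one arm's
food density exceeds the other's (most likely, probability matching), and
the Gittins-index benchmark. A noise parameter ``theta`` mixes any policy
with a fair coin: with probability theta the agent ignores the heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

from scipy import integrate, stats
from scipy.special import betaln
import numpy as np

from .arena import Treatment

MODEL_IDS = (
    "autocorrelation",
    "anti_autocorrelation",
    "most_successes",
    "highest_mean",
    "relative_successes",
    "relative_means",
    "most_likely",
    "probability_matching",
    "chemotaxis",
    "gittins",
)

#: Models whose noise-free output is an indicator (0, 1, or 0.5 at ties).
DETERMINISTIC_MODELS = (
    "autocorrelation",
    "anti_autocorrelation",
    "most_successes",
    "highest_mean",
    "most_likely",
    "chemotaxis",
    "gittins",
)

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PolicySpec:
    """A model identifier plus its noise level (and discount, for gittins)."""

    model_id: str
    theta: float = 0.0
    gittins_discount: float = 0.9

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id!r}; known: {MODEL_IDS}")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")
        if not 0.0 <= self.gittins_discount < 1.0:
            raise ValueError(f"gittins_discount must be in [0, 1), got {self.gittins_discount}")


@dataclass(frozen=True)
class BeliefState:
    """The agent's experience summary.

    ``a_*`` count rewarding sites encountered per arm, ``b_*`` blank sites,
    each including one pseudo-observation (so all stay >= 1); ``pos_*`` are
    leading-edge site indices (0 = arm not yet entered). With unit
    increments, ``a + b - 2`` equals the number of sites discovered on an
    arm; graded (magnitude-weighted) reward increments relax that identity
    for non-binary arenas.
    """

    a_r: float = 1.0
    a_l: float = 1.0
    b_r: float = 1.0
    b_l: float = 1.0
    pos_r: int = 0
    pos_l: int = 0
    last_move: str | None = None
    last_rewarded: bool | None = None

    def __post_init__(self) -> None:
        if min(self.a_r, self.a_l, self.b_r, self.b_l) < 1.0:
            raise ValueError("counts include a pseudo-observation and must stay >= 1")
        if self.last_move not in (None, "left", "right"):
            raise ValueError(f"last_move must be None/'left'/'right', got {self.last_move!r}")

    def mirrored(self) -> "BeliefState":
        """Swap the two arms (for symmetry checks and custom models)."""
        flip = {"left": "right", "right": "left", None: None}
        return BeliefState(
            a_r=self.a_l,
            a_l=self.a_r,
            b_r=self.b_l,
            b_l=self.b_r,
            pos_r=self.pos_l,
            pos_l=self.pos_r,
            last_move=flip[self.last_move],
            last_rewarded=self.last_rewarded,
        )


def init_state() -> BeliefState:
    """Fresh belief: one pseudo-observation per count, no arm entered."""
    return BeliefState()


def initialize_on_arena(
    state: BeliefState,
    treatment: Treatment,
    graded: bool = True,
    reference: float = 0.05,
) -> BeliefState:
    """Consume the guaranteed site-1 reward on both arms.

    Site 1 on each arm always carries food, so after initialisation both
    leading edges sit at site 1 and both success counts have been
    incremented — by exactly 1 on standard 5% sites, or by
    magnitude/reference under graded updates on non-binary arenas.
    """
    if state.pos_r != 0 or state.pos_l != 0:
        raise ValueError("initialize_on_arena requires a fresh state (pos 0 on both arms)")
    w_r = _success_increment(treatment.right_arm.sites[0], graded, reference)
    w_l = _success_increment(treatment.left_arm.sites[0], graded, reference)
    return replace(state, a_r=state.a_r + w_r, a_l=state.a_l + w_l, pos_r=1, pos_l=1)


def _success_increment(magnitude: float, graded: bool, reference: float) -> float:
    if magnitude <= 0:
        raise ValueError("site 1 must be rewarding")
    return magnitude / reference if graded else 1.0


def update_state(
    state: BeliefState,
    move: str,
    rewarded: bool | float,
    arm_length: int | None = None,
) -> BeliefState:
    """Advance one site on the moved arm and record the outcome.

    ``rewarded`` may be a boolean (unit increment) or a non-negative float
    weight for graded updates; zero means a blank site (failure count + 1).
    """
    if move not in ("left", "right"):
        raise ValueError(f"move must be 'left' or 'right', got {move!r}")
    w = float(rewarded)
    if w < 0:
        raise ValueError("reward weight must be non-negative")
    got_food = w > 0
    if move == "right":
        if arm_length is not None and state.pos_r + 1 > arm_length:
            raise ValueError("move would extend past the end of the right arm")
        return replace(
            state,
            a_r=state.a_r + w if got_food else state.a_r,
            b_r=state.b_r if got_food else state.b_r + 1,
            pos_r=state.pos_r + 1,
            last_move="right",
            last_rewarded=got_food,
        )
    if arm_length is not None and state.pos_l + 1 > arm_length:
        raise ValueError("move would extend past the end of the left arm")
    return replace(
        state,
        a_l=state.a_l + w if got_food else state.a_l,
        b_l=state.b_l if got_food else state.b_l + 1,
        pos_l=state.pos_l + 1,
        last_move="left",
        last_rewarded=got_food,
    )


# --- beta superiority -------------------------------------------------------


@lru_cache(maxsize=200_000)
def _beta_superiority_int(a_r: int, b_r: int, a_l: int, b_l: int) -> float:
    """P(X_R > X_L), X ~ Beta, by the exact finite sum for integer counts.

    P(X1 > X2) = sum_{i=0}^{a1-1} B(a2+i, b1+b2) / ((b1+i) B(1+i, b1) B(a2, b2)).
    """
    total = 0.0
    log_b22 = betaln(a_l, b_l)
    for i in range(a_r):
        total += float(
            np.exp(betaln(a_l + i, b_r + b_l) - np.log(b_r + i) - betaln(1 + i, b_r) - log_b22)
        )
    return total


def beta_superiority(a_r: float, b_r: float, a_l: float, b_l: float) -> float:
    """Posterior probability that the right arm's food density exceeds the left's.

    Densities carry independent Beta(a, b) posteriors (uniform prior plus the
    observed success/failure counts). Integer counts use an exact finite sum;
    otherwise adaptive quadrature of pdf_R(x) * cdf_L(x). Swapping the arms
    maps the result to its complement exactly.
    """
    if min(a_r, b_r, a_l, b_l) <= 0:
        raise ValueError("all counts must be positive")
    if (a_r, b_r) == (a_l, b_l):
        return 0.5
    # canonical ordering guarantees exact p -> 1 - p under arm swap
    if (a_r, b_r) < (a_l, b_l):
        return 1.0 - beta_superiority(a_l, b_l, a_r, b_r)
    if all(float(x).is_integer() for x in (a_r, b_r, a_l, b_l)):
        return min(1.0, max(0.0, _beta_superiority_int(int(a_r), int(b_r), int(a_l), int(b_l))))
    val, _ = integrate.quad(
        lambda x: stats.beta.pdf(x, a_r, b_r) * stats.beta.cdf(x, a_l, b_l),
        0.0,
        1.0,
        epsabs=1e-8,
    )
    return min(1.0, max(0.0, val))


# --- the model family -------------------------------------------------------


def _indicator(diff: float) -> float:
    if diff > _TIE_TOL:
        return 1.0
    if diff < -_TIE_TOL:
        return 0.0
    return 0.5


def _p_autocorrelation(s: BeliefState, fr: bool, fl: bool, spec: PolicySpec) -> float:
    if s.last_move is None:
        return 0.5
    return 1.0 if s.last_move == "right" else 0.0


def _p_anti_autocorrelation(s: BeliefState, fr: bool, fl: bool, spec: PolicySpec) -> float:
    if s.last_move is None:
        return 0.5
    return 1.0 if s.last_move == "left" else 0.0


def _p_most_successes(s: BeliefState, fr: bool, fl: bool, spec: PolicySpec) -> float:
    return _indicator(s.a_r - s.a_l)


def _p_highest_mean(s: BeliefState, fr: bool, fl: bool, spec: PolicySpec) -> float:
    # compare a_r/(a_r+b_r) vs a_l/(a_l+b_l) by cross-multiplication (exact for ints)
    return _indicator(s.a_r * (s.a_l + s.b_l) - s.a_l * (s.a_r + s.b_r))


def _p_relative_successes(s: BeliefState, fr: bool, fl: bool, spec: PolicySpec) -> float:
    return s.a_r / (s.a_r + s.a_l)


def _p_relative_means(s: BeliefState, fr: bool, fl: bool, spec: PolicySpec) -> float:
    m_r = s.a_r / (s.a_r + s.b_r)
    m_l = s.a_l / (s.a_l + s.b_l)
    return m_r / (m_r + m_l)


def _p_most_likely(s: BeliefState, fr: bool, fl: bool, spec: PolicySpec) -> float:
    return _indicator(beta_superiority(s.a_r, s.b_r, s.a_l, s.b_l) - 0.5)


def _p_probability_matching(s: BeliefState, fr: bool, fl: bool, spec: PolicySpec) -> float:
    return beta_superiority(s.a_r, s.b_r, s.a_l, s.b_l)


def _p_chemotaxis(s: BeliefState, fr: bool, fl: bool, spec: PolicySpec) -> float:
    # parameter-free attraction to food at the next available site
    if fr and not fl:
        return 1.0
    if fl and not fr:
        return 0.0
    return 0.5


def _p_gittins(s: BeliefState, fr: bool, fl: bool, spec: PolicySpec) -> float:
    from . import gittins as _g  # local import to avoid a module cycle

    return _g.gittins_policy(s, discount=spec.gittins_discount)


_DISPATCH = {
    "autocorrelation": _p_autocorrelation,
    "anti_autocorrelation": _p_anti_autocorrelation,
    "most_successes": _p_most_successes,
    "highest_mean": _p_highest_mean,
    "relative_successes": _p_relative_successes,
    "relative_means": _p_relative_means,
    "most_likely": _p_most_likely,
    "probability_matching": _p_probability_matching,
    "chemotaxis": _p_chemotaxis,
    "gittins": _p_gittins,
}


def base_prob(
    spec: PolicySpec,
    state: BeliefState,
    food_next_r: bool = False,
    food_next_l: bool = False,
) -> float:
    """Noise-free probability of moving right under ``spec`` in ``state``.

    ``food_next_*`` indicate food at the next available site on each arm
    (False past the arm end); only the chemotaxis model consults them.
    """
    try:
        fn = _DISPATCH[spec.model_id]
    except KeyError:  # pragma: no cover - PolicySpec already validates
        raise ValueError(f"unknown model {spec.model_id!r}") from None
    p = fn(state, bool(food_next_r), bool(food_next_l), spec)
    if not 0.0 <= p <= 1.0:  # pragma: no cover - defensive
        raise RuntimeError(f"model {spec.model_id} produced invalid probability {p}")
    return p


def apply_noise(p: float, theta: float) -> float:
    """Mix a policy probability with a fair coin: (1 - theta) * p + theta / 2."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    return (1.0 - theta) * p + theta / 2.0


def move_prob(
    spec: PolicySpec,
    state: BeliefState,
    food_next_r: bool = False,
    food_next_l: bool = False,
) -> float:
    """Noise-mixed probability of moving right (the sampling distribution)."""
    return apply_noise(base_prob(spec, state, food_next_r, food_next_l), spec.theta)
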