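"""Bayesian model selection over the behavioural model family.

For each candidate model, the evidence (marginal likelihood) of a set of
trajectories is the per-move likelihood of every realized move under the
noise-mixed policy, integrated over the noise parameter theta with a
uniform prior on [0, 1] (trapezoid quadrature on a theta grid, log-sum-exp
stabilized). Posterior model probabilities follow from a uniform prior
over the model set. Because the noise mixture is affine in theta, the
noise-free probability of each realized move is computed once per model
and the grid evaluation is vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .arena import Treatment
from .decision_models import (
    MODEL_IDS,
    PolicySpec,
    base_prob,
    init_state,
    initialize_on_arena,
    update_state,
)
from .simulator import GRADED_REFERENCE, Trajectory


class TrajectoryMismatchError(ValueError):
    """A trajectory is inconsistent with its arena geometry."""


@dataclass
class ModelEvidence:
    model_id: str
    log_marginal_likelihood: float
    theta_grid: np.ndarray
    per_theta_loglik: np.ndarray
    theta_hat: float
    posterior_probability: float | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "log_evidence": self.log_marginal_likelihood,
            "posterior": self.posterior_probability,
            "theta_hat": self.theta_hat,
        }


def realized_move_probs(
    model_id: str,
    trajectory: Trajectory,
    treatment: Treatment | None = None,
    gittins_discount: float = 0.9,
    graded: bool = True,
) -> np.ndarray:
    """Noise-free model probability of each realized, non-forced move.

    Replays the trajectory against its arena, consuming the same graded or
    binary reward updates the simulator applies. Forced moves (the other arm
    exhausted) carry probability one and are omitted from the returned array.
    """
    treatment = treatment if treatment is not None else trajectory.treatment
    if treatment is None:
        raise TrajectoryMismatchError(
            f"trajectory {trajectory.seed!r} carries no treatment and none was supplied"
        )
    if treatment.name != trajectory.treatment_name:
        raise TrajectoryMismatchError(
            f"trajectory is from {trajectory.treatment_name!r}, arena is {treatment.name!r}"
        )
    treatment = treatment.with_hq_side(trajectory.hq_side)
    arm_len = treatment.arm_length
    left, right = treatment.left_arm, treatment.right_arm
    spec = PolicySpec(model_id, 0.0, gittins_discount)
    state = initialize_on_arena(init_state(), treatment, graded=graded, reference=GRADED_REFERENCE)
    probs: list[float] = []
    for move in trajectory.moves:
        expected = (state.pos_r if move.arm == "right" else state.pos_l) + 1
        if move.site != expected:
            raise TrajectoryMismatchError(
                f"step {move.step}: site {move.site} on {move.arm} arm, expected {expected}"
            )
        if move.site > arm_len:
            raise TrajectoryMismatchError(
                f"step {move.step}: site {move.site} beyond arm length {arm_len}"
            )
        forced = state.pos_r >= arm_len or state.pos_l >= arm_len
        if not forced:
            food_r = right.sites[state.pos_r] > 0
            food_l = left.sites[state.pos_l] > 0
            p = base_prob(spec, state, food_r, food_l)
            probs.append(p if move.arm == "right" else 1.0 - p)
        reward = move.reward
        w = (reward / GRADED_REFERENCE if graded else 1.0) if reward > 0 else 0.0
        state = update_state(state, move.arm, w, arm_length=arm_len)
    return np.asarray(probs)


def trajectory_loglik(
    spec: PolicySpec,
    trajectory: Trajectory,
    treatment: Treatment | None = None,
    graded: bool = True,
) -> float:
    """Log-likelihood of one trajectory under the noise-mixed policy."""
    q = realized_move_probs(
        spec.model_id, trajectory, treatment, spec.gittins_discount, graded=graded
    )
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log((1.0 - spec.theta) * q + spec.theta / 2.0)))


def _pooled_move_probs(
    model_id: str,
    trajectories: Iterable[Trajectory],
    gittins_discount: float,
    graded: bool,
) -> np.ndarray:
    chunks = [
        realized_move_probs(model_id, t, gittins_discount=gittins_discount, graded=graded)
        for t in trajectories
        if not t.excluded
    ]
    if not chunks:
        raise ValueError("no non-excluded trajectories supplied")
    return np.concatenate(chunks)


def marginal_loglik(
    model_id: str,
    trajectories: Sequence[Trajectory],
    theta_grid_size: int = 101,
    gittins_discount: float = 0.9,
    graded: bool = True,
) -> ModelEvidence:
    """Evidence of ``model_id`` with theta integrated out (uniform prior).

    One global theta is shared across all trajectories and treatments; the
    1-D integral uses trapezoid weights on an even grid, combined in log
    space. Also reports the grid argmax theta-hat.
    """
    if theta_grid_size < 3:
        raise ValueError("theta_grid_size must be >= 3")
    q = _pooled_move_probs(model_id, trajectories, gittins_discount, graded)
    grid = np.linspace(0.0, 1.0, theta_grid_size)
    with np.errstate(divide="ignore"):
        per_theta = np.log(
            (1.0 - grid)[:, None] * q[None, :] + grid[:, None] / 2.0
        ).sum(axis=1)
    weights = np.full(theta_grid_size, 1.0 / (theta_grid_size - 1))
    weights[0] = weights[-1] = 0.5 / (theta_grid_size - 1)
    with np.errstate(divide="ignore"):
        log_evidence = float(logsumexp(per_theta + np.log(weights)))
    if not np.isfinite(log_evidence) and np.all(np.isneginf(per_theta)):
        import warnings

        warnings.warn(f"model {model_id!r}: likelihood is zero at every grid point")
    theta_hat = float(grid[int(np.argmax(per_theta))])
    return ModelEvidence(model_id, log_evidence, grid, per_theta, theta_hat)


def select_model(
    trajectories: Sequence[Trajectory],
    models: Sequence[str] | None = None,
    theta_grid_size: int = 101,
    gittins_discount: float = 0.9,
    graded: bool = True,
) -> list[ModelEvidence]:
    """Rank candidate models by marginal likelihood (uniform model prior).

    Returns evidences sorted by descending evidence (ties broken
    lexicographically by model id), with posterior probabilities normalized
    over the supplied model set.
    """
    models = tuple(models) if models is not None else MODEL_IDS
    if not models:
        raise ValueError("at least one model is required")
    evidences = [
        marginal_loglik(m, trajectories, theta_grid_size, gittins_discount, graded)
        for m in models
    ]
    logs = np.array([e.log_marginal_likelihood for e in evidences])
    if np.all(np.isneginf(logs)):
        post = np.full(len(logs), 1.0 / len(logs))
    else:
        post = np.exp(logs - logsumexp(logs))
    for e, p in zip(evidences, post):
        e.posterior_probability = float(p)
    evidences.sort(key=lambda e: (-e.log_marginal_likelihood, e.model_id))
    return evidences
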