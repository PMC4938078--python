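"""Forward simulation of policies on arenas, and the study's summary statistics.

A trajectory is one replicate: starting with both leading edges on the
guaranteed site-1 food sites, the agent extends exactly one arm per step,
sampling the direction from the noise-mixed policy, until one arm's last
site is reached — the "chosen" arm. Two summaries mirror the experimental
read-outs: the discovery-difference curve (HQ minus LQ sites discovered at
the moment each site rank is first attained, averaged over replicates with
a 1.96 s.e. band) and the proportion of replicates finishing the HQ arm
first, with an exact binomial test against chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .arena import Treatment
from .decision_models import (
    BeliefState,
    PolicySpec,
    apply_noise,
    base_prob,
    init_state,
    initialize_on_arena,
    update_state,
)

GRADED_REFERENCE = 0.05  # the standard 5% oat-agar site carries unit weight


class Move(NamedTuple):
    step: int
    arm: str  # "left" | "right"
    site: int  # 1-based site index reached on that arm
    reward: float  # oat concentration at the site (0 = blank)


@dataclass
class Trajectory:
    """One replicate's move/reward sequence and its outcome."""

    treatment_name: str
    hq_side: str
    moves: list[Move]
    end_cause: str  # "hq_end_first" | "lq_end_first"
    seed: int | None = None
    excluded: bool = False
    treatment: Treatment | None = field(default=None, compare=False, repr=False)

    @property
    def n_moves(self) -> int:
        return len(self.moves)

    def final_positions(self) -> tuple[int, int]:
        """(hq, lq) leading-edge positions at termination."""
        pos = {"left": 1, "right": 1}
        for m in self.moves:
            pos[m.arm] = m.site
        hq = pos[self.hq_side]
        lq = pos["left" if self.hq_side == "right" else "right"]
        return hq, lq


def simulate_trajectory(
    spec: PolicySpec,
    treatment: Treatment,
    seed: int | np.random.SeedSequence | None = None,
    graded: bool = True,
) -> Trajectory:
    """Simulate one replicate of ``spec`` exploring ``treatment``.

    Terminates the first time either arm's last site is reached. Graded
    updates weight each food encounter by magnitude / 5%; on binary (5%)
    arenas this is identical to unit increments.
    """
    rng = np.random.default_rng(seed)
    arm_len = treatment.arm_length
    left, right = treatment.left_arm, treatment.right_arm
    state = initialize_on_arena(init_state(), treatment, graded=graded, reference=GRADED_REFERENCE)
    moves: list[Move] = []
    step = 0
    while True:
        step += 1
        if state.pos_r >= arm_len:  # pragma: no cover - termination precedes exhaustion
            p = 0.0
        elif state.pos_l >= arm_len:  # pragma: no cover
            p = 1.0
        else:
            food_r = right.sites[state.pos_r] > 0
            food_l = left.sites[state.pos_l] > 0
            p = apply_noise(base_prob(spec, state, food_r, food_l), spec.theta)
        go_right = rng.random() < p
        arm = "right" if go_right else "left"
        layout = right if go_right else left
        site = (state.pos_r if go_right else state.pos_l) + 1
        reward = layout.sites[site - 1]
        w = (reward / GRADED_REFERENCE if graded else 1.0) if reward > 0 else 0.0
        state = update_state(state, arm, w, arm_length=arm_len)
        moves.append(Move(step, arm, site, float(reward)))
        if site == arm_len:
            end_cause = "hq_end_first" if arm == treatment.hq_side else "lq_end_first"
            break
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return Trajectory(
        treatment_name=treatment.name,
        hq_side=treatment.hq_side,
        moves=moves,
        end_cause=end_cause,
        seed=int(seed_int) if seed_int is not None else None,
        treatment=treatment,
    )


@dataclass
class DiscoveryCurve:
    """Mean HQ-minus-LQ site-discovery difference at each discovery rank."""

    ranks: np.ndarray  # 1..L
    mean_diff: np.ndarray
    half_width: np.ndarray  # 1.96 * s.e. across replicates
    n: np.ndarray  # replicates contributing at each rank

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": self.ranks,
                "mean_diff": self.mean_diff,
                "half_width": self.half_width,
                "n": self.n,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _active(trajectories: Iterable[Trajectory]) -> list[Trajectory]:
    return [t for t in trajectories if not t.excluded]


def first_discovery_difference(
    trajectories: Sequence[Trajectory],
    carry_forward: bool = True,
) -> DiscoveryCurve:
    """Discovery-difference curve across replicates of one treatment.

    For each rank i, the difference (HQ sites discovered) - (LQ sites
    discovered) is recorded at the moment the i-th site is first reached on
    either arm. Replicates that terminated before rank i contribute their
    final difference when ``carry_forward`` (default); otherwise they drop
    out of the mean at later ranks.
    """
    trajs = _active(trajectories)
    if not trajs:
        raise ValueError("first_discovery_difference requires at least one trajectory")
    names = {t.treatment_name for t in trajs}
    if len(names) > 1:
        raise ValueError(f"trajectories span multiple treatments: {sorted(names)}")
    arm_len = max(
        (t.treatment.arm_length for t in trajs if t.treatment is not None),
        default=max(m.site for t in trajs for m in t.moves),
    )
    rows = np.full((len(trajs), arm_len), np.nan)
    for k, t in enumerate(trajs):
        hq_arm = t.hq_side
        pos_hq, pos_lq = 1, 1
        max_rank = 1
        rows[k, 0] = 0.0
        for m in t.moves:
            if m.arm == hq_arm:
                pos_hq = m.site
            else:
                pos_lq = m.site
            top = max(pos_hq, pos_lq)
            if top > max_rank:
                max_rank = top
                rows[k, top - 1] = pos_hq - pos_lq
        if carry_forward and max_rank < arm_len:
            rows[k, max_rank:] = rows[k, max_rank - 1]
    n = np.sum(~np.isnan(rows), axis=0)
    mean = np.where(n > 0, np.nanmean(rows, axis=0), np.nan)
    half = np.zeros(arm_len)
    for j in range(arm_len):
        if n[j] >= 2:
            sd = float(np.nanstd(rows[:, j], ddof=1))
            half[j] = 1.96 * sd / np.sqrt(n[j])
    return DiscoveryCurve(np.arange(1, arm_len + 1), mean, half, n)


def proportion_hq_first(trajectories: Sequence[Trajectory]) -> tuple[float, float]:
    """(proportion of replicates finishing the HQ arm first, exact binomial p vs 0.5)."""
    trajs = _active(trajectories)
    if not trajs:
        raise ValueError("proportion_hq_first requires at least one trajectory")
    for t in trajs:
        if t.treatment is not None and t.treatment.is_equal:
            raise ValueError(
                f"treatment {t.treatment_name!r} has equally rewarding arms; HQ is undefined"
            )
    k = sum(t.end_cause == "hq_end_first" for t in trajs)
    n = len(trajs)
    result = stats.binomtest(k, n, 0.5, alternative="two-sided")
    return k / n, float(result.pvalue)


def compare_performance(
    specs: Sequence[PolicySpec],
    bandit: tuple[float, float],
    n_steps: int = 100,
    n_sims: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean cumulative reward of each policy on a stationary Bernoulli bandit.

    ``bandit`` is (left, right) reward probability; there is no arm
    exhaustion, so this isolates pure exploration/exploitation quality. The
    Gittins policy serves as the optimal benchmark. Returns a DataFrame
    indexed by model id with columns mean_reward and se.
    """
    p_left, p_right = bandit
    if not (0.0 <= p_left <= 1.0 and 0.0 <= p_right <= 1.0):
        raise ValueError("reward probabilities must be in [0, 1]")
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(specs))
    records = []
    for spec, child in zip(specs, children):
        if spec.model_id == "gittins":
            from .gittins import get_table

            get_table(spec.gittins_discount).bulk_fill(n_steps + 3)
        rng = np.random.default_rng(child)
        totals = np.empty(n_sims)
        for i in range(n_sims):
            state = init_state()
            total = 0
            for _ in range(n_steps):
                p = apply_noise(base_prob(spec, state), spec.theta)
                go_right = rng.random() < p
                rewarded = rng.random() < (p_right if go_right else p_left)
                state = update_state(state, "right" if go_right else "left", rewarded)
                total += rewarded
            totals[i] = total
        records.append(
            {
                "model_id": spec.model_id,
                "mean_reward": float(totals.mean()),
                "se": float(totals.std(ddof=1) / np.sqrt(n_sims)),
            }
        )
    return pd.DataFrame(records).set_index("model_id")
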