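"""Two-armed arena construction.

An arena is a pair of linear arms radiating from a central start block.
Each arm is a row of 1 mm agar sites; a site is either blank agar
(magnitude 0) or oat-agar carrying a food reward whose magnitude is the
oat concentration as a fraction w/v (the standard food site is 5% = 0.05).
Site 1 — the site adjacent to the start block — always carries food, so
that a foraging cell initialises exploration on both arms.

The treatment registry enumerates the choice scenarios of the study:
equal-arm baselines, even and random binary layouts at 1:2 and 11:16
quality ratios, and a non-binary scenario where both arms have the same
number of food sites but the high-quality (HQ) arm carries twice the
total oat concentration of the low-quality (LQ) arm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import numpy as np

DEFAULT_ARM_LENGTH = 31
DEFAULT_MAGNITUDE = 0.05  # 5% w/v oat-agar, the standard food site
NONBINARY_SITE_RANGE = (0.01, 0.08)
DEFAULT_NONBINARY_TOTAL = 0.40  # 8 sites averaging the standard 5% concentration

SIDES = ("left", "right")


@dataclass(frozen=True)
class ArmLayout:
    """Ordered reward magnitudes for one arm.

    ``sites[k]`` is the oat concentration at site ``k + 1`` (sites are
    1-based, site 1 adjacent to the start block).
    """

    sites: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ValueError("an arm needs at least 2 sites")
        if any(m < 0 for m in self.sites):
            raise ValueError("reward magnitudes must be non-negative")
        if self.sites[0] <= 0:
            raise ValueError("site 1 must be rewarding")

    @property
    def arm_length(self) -> int:
        return len(self.sites)

    @property
    def reward_positions(self) -> tuple[int, ...]:
        """1-based indices of rewarding sites."""
        return tuple(i + 1 for i, m in enumerate(self.sites) if m > 0)

    @property
    def n_rewards(self) -> int:
        return len(self.reward_positions)

    @property
    def total_reward(self) -> float:
        return float(sum(self.sites))

    @property
    def is_binary(self) -> bool:
        """True when all rewarding sites share a single magnitude."""
        return len({m for m in self.sites if m > 0}) == 1


@dataclass(frozen=True)
class Treatment:
    """A named pair of arm layouts with an HQ/LQ designation.

    ``hq_side`` records which physical side carries the HQ layout for a
    given replicate; it is randomised between replicates in the study
    design, so it is assignable via :meth:`with_hq_side`.
    """

    name: str
    hq_arm: ArmLayout
    lq_arm: ArmLayout
    hq_side: str = "right"
    layout_kind: str = "even"  # even | random | nonbinary
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.hq_side not in SIDES:
            raise ValueError(f"hq_side must be one of {SIDES}, got {self.hq_side!r}")
        if self.hq_arm.arm_length != self.lq_arm.arm_length:
            raise ValueError("arms must have equal length")
        if self.hq_arm.total_reward < self.lq_arm.total_reward - 1e-12:
            raise ValueError("HQ arm must carry at least as much total reward as LQ")

    @property
    def arm_length(self) -> int:
        return self.hq_arm.arm_length

    @property
    def is_equal(self) -> bool:
        """True when the two arms are equally rewarding (no HQ/LQ distinction)."""
        return (
            math.isclose(self.hq_arm.total_reward, self.lq_arm.total_reward)
            and self.hq_arm.n_rewards == self.lq_arm.n_rewards
        )

    @property
    def left_arm(self) -> ArmLayout:
        return self.hq_arm if self.hq_side == "left" else self.lq_arm

    @property
    def right_arm(self) -> ArmLayout:
        return self.hq_arm if self.hq_side == "right" else self.lq_arm

    def arm(self, side: str) -> ArmLayout:
        if side == "left":
            return self.left_arm
        if side == "right":
            return self.right_arm
        raise ValueError(f"unknown side {side!r}")

    def with_hq_side(self, side: str) -> "Treatment":
        return replace(self, hq_side=side)


def make_even_layout(
    arm_length: int = DEFAULT_ARM_LENGTH,
    n_rewards: int = 8,
    magnitude: float = DEFAULT_MAGNITUDE,
) -> ArmLayout:
    """Layout with ``n_rewards`` food sites spread maximally evenly.

    Reward k of n (k = 0..n-1) occupies site 1 + round(k*(L-1)/(n-1));
    n = 1 places food on site 1 only. Rounding is half-up so the grid is
    strictly increasing whenever n <= L. Deterministic.
    """
    if not 1 <= n_rewards <= arm_length:
        raise ValueError(f"n_rewards must be in [1, {arm_length}], got {n_rewards}")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    if n_rewards == 1:
        positions = {1}
    else:
        step = (arm_length - 1) / (n_rewards - 1)
        positions = {1 + math.floor(k * step + 0.5) for k in range(n_rewards)}
    sites = [magnitude if (i + 1) in positions else 0.0 for i in range(arm_length)]
    return ArmLayout(tuple(sites))


def make_random_layout(
    arm_length: int = DEFAULT_ARM_LENGTH,
    n_rewards: int = 8,
    magnitude: float = DEFAULT_MAGNITUDE,
    seed: int | np.random.SeedSequence | None = None,
) -> ArmLayout:
    """Layout with food on site 1 and ``n_rewards - 1`` further sites drawn
    uniformly without replacement from sites 2..arm_length."""
    if not 1 <= n_rewards <= arm_length:
        raise ValueError(f"n_rewards must be in [1, {arm_length}], got {n_rewards}")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    rng = np.random.default_rng(seed)
    positions = {1}
    if n_rewards > 1:
        extra = rng.choice(np.arange(2, arm_length + 1), size=n_rewards - 1, replace=False)
        positions.update(int(p) for p in extra)
    sites = [magnitude if (i + 1) in positions else 0.0 for i in range(arm_length)]
    return ArmLayout(tuple(sites))


def _rescale_to_total(
    values: np.ndarray, total: float, lo: float, hi: float, max_iter: int = 100, tol: float = 1e-9
) -> np.ndarray:
    """Scale ``values`` to sum to ``total``; keep each in [lo, hi] when feasible.

    When ``total`` lies outside [n*lo, n*hi] the range cannot be honoured and a
    pure rescale is returned (the total — and hence the HQ:LQ ratio — wins).
    """
    n = len(values)
    out = values * (total / values.sum())
    if not (n * lo <= total <= n * hi):
        return out
    for _ in range(max_iter):
        clipped = np.clip(out, lo, hi)
        err = total - clipped.sum()
        if abs(err) < tol:
            return clipped
        # redistribute the residual over entries with slack in the needed direction
        if err > 0:
            free = clipped < hi - 1e-15
        else:
            free = clipped > lo + 1e-15
        if not free.any():  # pragma: no cover - feasible totals always leave slack
            return clipped
        out = clipped.copy()
        out[free] += err * (clipped[free] / clipped[free].sum())
    return np.clip(out, lo, hi)


def make_nonbinary_pair(
    arm_length: int = DEFAULT_ARM_LENGTH,
    n_rewards: int = 8,
    hq_total: float = DEFAULT_NONBINARY_TOTAL,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[ArmLayout, ArmLayout]:
    """HQ/LQ pair with equal food-site counts but a 2:1 total-concentration ratio.

    Both arms get ``n_rewards`` food sites at random positions (site 1
    included). Magnitudes are drawn uniformly on [1%, 8%] and rescaled so the
    HQ sum equals ``hq_total`` and the LQ sum equals ``hq_total / 2`` — the
    2:1 ratio is exact; per-site magnitudes stay within [1%, 8%] whenever the
    target total permits.
    """
    if n_rewards < 1:
        raise ValueError("n_rewards must be >= 1")
    if hq_total <= 0:
        raise ValueError("hq_total must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = NONBINARY_SITE_RANGE
    arms = []
    for total in (hq_total, hq_total / 2.0):
        positions = {1}
        if n_rewards > 1:
            extra = rng.choice(np.arange(2, arm_length + 1), size=n_rewards - 1, replace=False)
            positions.update(int(p) for p in extra)
        mags = _rescale_to_total(rng.uniform(lo, hi, size=n_rewards), total, lo, hi)
        sites = [0.0] * arm_length
        for pos, mag in zip(sorted(positions), mags):
            sites[pos - 1] = float(mag)
        arms.append(ArmLayout(tuple(sites)))
    return arms[0], arms[1]


# --- treatment registry ----------------------------------------------------

# name -> (lq spec, hq spec, kind); binary specs are (n_rewards, even?) pairs
_BINARY_TREATMENTS: dict[str, tuple[int, int, str]] = {
    "31_vs_31": (31, 31, "even"),
    "1_vs_1": (1, 1, "even"),
    "8e_vs_8e": (8, 8, "even"),
    "8r_vs_8r": (8, 8, "random"),
    "1_vs_8e": (1, 8, "even"),
    "4e_vs_8e": (4, 8, "even"),
    "4r_vs_8r": (4, 8, "random"),
    "8e_vs_16e": (8, 16, "even"),
    "8r_vs_16r": (8, 16, "random"),
    "11e_vs_16e": (11, 16, "even"),
    "11r_vs_16r": (11, 16, "random"),
}

TREATMENT_NAMES: tuple[str, ...] = tuple(_BINARY_TREATMENTS) + ("nonbinary",)

#: Treatments with a genuine HQ/LQ quality difference.
UNEQUAL_TREATMENTS: tuple[str, ...] = (
    "1_vs_8e",
    "4e_vs_8e",
    "4r_vs_8r",
    "8e_vs_16e",
    "8r_vs_16r",
    "11e_vs_16e",
    "11r_vs_16r",
    "nonbinary",
)


def make_treatment(
    name: str,
    seed: int | None = None,
    hq_side: str = "right",
    arm_length: int = DEFAULT_ARM_LENGTH,
    magnitude: float = DEFAULT_MAGNITUDE,
) -> Treatment:
    """Instantiate a named treatment.

    Random and non-binary layouts require ``seed``; layouts are regenerated
    per replicate in the study design, so each replicate gets its own seed.
    """
    if name == "nonbinary":
        if seed is None:
            raise ValueError("treatment 'nonbinary' requires a seed")
        hq, lq = make_nonbinary_pair(arm_length, 8, DEFAULT_NONBINARY_TOTAL, seed)
        return Treatment(name, hq, lq, hq_side, "nonbinary", seed)
    try:
        n_lq, n_hq, kind = _BINARY_TREATMENTS[name]
    except KeyError:
        raise KeyError(f"unknown treatment {name!r}; known: {sorted(TREATMENT_NAMES)}") from None
    if kind == "even":
        lq = make_even_layout(arm_length, n_lq, magnitude)
        hq = make_even_layout(arm_length, n_hq, magnitude)
        return Treatment(name, hq, lq, hq_side, "even", None)
    if seed is None:
        raise ValueError(f"treatment {name!r} has random layouts and requires a seed")
    ss = np.random.SeedSequence(seed)
    lq_ss, hq_ss = ss.spawn(2)
    lq = make_random_layout(arm_length, n_lq, magnitude, lq_ss)
    hq = make_random_layout(arm_length, n_hq, magnitude, hq_ss)
    return Treatment(name, hq, lq, hq_side, "random", seed)


def treatment_registry() -> dict[str, Callable[..., Treatment]]:
    """Mapping of treatment name to a constructor ``f(seed=None, hq_side='right')``."""

    def _factory(name: str) -> Callable[..., Treatment]:
        def build(seed: int | None = None, hq_side: str = "right", **kw) -> Treatment:
            return make_treatment(name, seed=seed, hq_side=hq_side, **kw)

        build.__name__ = f"make_{name}"
        return build

    return {name: _factory(name) for name in TREATMENT_NAMES}


# --- JSON serialization ----------------------------------------------------


def treatment_to_dict(t: Treatment) -> dict:
    return {
        "name": t.name,
        "arm_length": t.arm_length,
        "left": list(t.left_arm.sites),
        "right": list(t.right_arm.sites),
        "hq_side": t.hq_side,
        "layout_kind": t.layout_kind,
        "seed": t.seed,
    }


def treatment_from_dict(d: dict) -> Treatment:
    left = ArmLayout(tuple(d["left"]))
    right = ArmLayout(tuple(d["right"]))
    hq_side = d["hq_side"]
    hq, lq = (left, right) if hq_side == "left" else (right, left)
    return Treatment(
        name=d["name"],
        hq_arm=hq,
        lq_arm=lq,
        hq_side=hq_side,
        layout_kind=d.get("layout_kind", "even"),
        seed=d.get("seed"),
    )


def write_arena_json(t: Treatment, path: str | Path) -> None:
    Path(path).write_text(json.dumps(treatment_to_dict(t), indent=2) + "\n")


def read_arena_json(path: str | Path) -> Treatment:
    return treatment_from_dict(json.loads(Path(path).read_text()))
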