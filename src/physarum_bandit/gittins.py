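"""Gittins indices for Beta-Bernoulli one-armed bandits (calibration method).

The Gittins index of a belief state Beta(A, B) is the constant payoff rate
lambda* at which a decision-maker with geometric discount gamma is
indifferent between retiring on the constant arm (value lambda*/(1-gamma))
and pulling the risky arm once and continuing optimally. Playing the arm
with the highest index is the optimal stationary-bandit policy, which makes
it the performance benchmark against which the behavioural heuristics are
compared.

``gittins_index`` bisects on lambda, evaluating the one-armed stopping
problem by backward induction over the (A, B) lattice truncated at a
horizon where the discounted tail is negligible. ``GittinsTable.bulk_fill``
computes a whole lattice at once by sweeping a lambda grid (the
retire-minus-continue gap is piecewise linear in lambda, so the root is
recovered by local linear interpolation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .decision_models import BeliefState

_TRUNCATION_EPS = 1e-8
_HORIZON_CAP = 2000
_MAX_BISECT = 200


def _horizon(discount: float) -> int:
    """Smallest T with discount**T below the truncation tolerance (capped)."""
    if discount <= 0.0:
        return 1
    t = math.ceil(math.log(_TRUNCATION_EPS) / math.log(discount))
    return min(max(t, 1), _HORIZON_CAP)


def _continuation_value(a: float, b: float, lam: float, discount: float, horizon: int) -> float:
    """Value of pulling the Beta(a, b) arm once and then acting optimally.

    Backward induction over lattice levels s = a+b .. a+b+horizon; states past
    the horizon are valued by the myopic bound max(lam, mean)/(1-gamma).
    """
    g = discount
    s0 = a + b
    retire = lam / (1.0 - g)
    # terminal level: a' = a .. a + horizon
    a_vals = a + np.arange(horizon + 1, dtype=float)
    w = np.maximum(lam, a_vals / (s0 + horizon)) / (1.0 - g)
    for d in range(horizon - 1, 0, -1):
        a_vals = a + np.arange(d + 1, dtype=float)
        p = a_vals / (s0 + d)
        cont = p * (1.0 + g * w[1:]) + (1.0 - p) * g * w[:-1]
        w = np.maximum(retire, cont)
    p0 = a / s0
    return float(p0 * (1.0 + g * w[1]) + (1.0 - p0) * g * w[0])


def gittins_index(a: float, b: float, discount: float = 0.9, tol: float = 1e-4) -> float:
    """Gittins index of a Beta(a, b) Bernoulli arm under geometric discounting.

    Computed by bisection on the calibration payoff lambda; at discount 0 the
    index is the posterior mean a/(a+b) exactly.
    """
    if a < 1 or b < 1:
        raise ValueError("counts must be >= 1 (they include the pseudo-observation)")
    if not 0.0 <= discount < 1.0:
        raise ValueError(f"discount must be in [0, 1), got {discount}")
    if discount == 0.0:
        return a / (a + b)
    horizon = _horizon(discount)
    lo, hi = a / (a + b), 1.0
    for _ in range(_MAX_BISECT):
        if hi - lo <= tol:
            return 0.5 * (lo + hi)
        mid = 0.5 * (lo + hi)
        cont = _continuation_value(a, b, mid, discount, horizon)
        if cont > mid / (1.0 - discount):
            lo = mid
        else:
            hi = mid
    raise RuntimeError("gittins_index bisection failed to converge")  # pragma: no cover


@dataclass
class GittinsTable:
    """Memoized Gittins indices over integer (A, B) belief states."""

    discount: float = 0.9
    tol: float = 1e-4
    values: dict[tuple[int, int], float] = field(default_factory=dict)

    def index(self, a: float, b: float) -> float:
        """Index for (a, b); integer states are cached, the table extends on demand."""
        if float(a).is_integer() and float(b).is_integer():
            key = (int(a), int(b))
            if key not in self.values:
                self.values[key] = gittins_index(a, b, self.discount, self.tol)
            return self.values[key]
        return gittins_index(a, b, self.discount, self.tol)

    def bulk_fill(self, max_total: int, n_lambda: int = 801) -> "GittinsTable":
        """Fill every missing (a, b) with a + b <= max_total in one lattice sweep."""
        if self.discount == 0.0:
            for s in range(2, max_total + 1):
                for a in range(1, s):
                    self.values.setdefault((a, s - a), a / s)
            return self
        g = self.discount
        horizon = _horizon(g)
        smax = max_total + horizon
        lam = np.linspace(0.0, 1.0, n_lambda)[:, None]
        retire = lam / (1.0 - g)
        # level smax: states a' = 1 .. smax-1
        a_vals = np.arange(1, smax, dtype=float)[None, :]
        w = np.maximum(lam, a_vals / smax) / (1.0 - g)
        gaps: dict[int, np.ndarray] = {}
        for s in range(smax - 1, 1, -1):
            a_vals = np.arange(1, s, dtype=float)[None, :]
            p = a_vals / s
            cont = p * (1.0 + g * w[:, 1:]) + (1.0 - p) * g * w[:, :-1]
            if s <= max_total:
                gaps[s] = cont - retire  # >0 where continuing beats retiring
            w = np.maximum(retire, cont)
        for s, gap in gaps.items():
            for col in range(s - 1):
                a = col + 1
                if (a, s - a) in self.values:
                    continue
                d = gap[:, col]
                k = int(np.count_nonzero(d > 0.0)) - 1  # last grid point still continuing
                if k < 0:  # pragma: no cover - gap is positive at lambda = 0
                    idx = 0.0
                elif k >= n_lambda - 1:  # pragma: no cover
                    idx = 1.0
                else:
                    lam_k, lam_k1 = lam[k, 0], lam[k + 1, 0]
                    idx = lam_k + d[k] * (lam_k1 - lam_k) / (d[k] - d[k + 1])
                self.values[(a, s - a)] = max(float(idx), a / s)
        return self

    def to_json(self, path: str | Path) -> None:
        payload = {
            "discount": self.discount,
            "tol": self.tol,
            "values": {f"{a},{b}": v for (a, b), v in sorted(self.values.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GittinsTable":
        d = json.loads(Path(path).read_text())
        values = {
            tuple(int(x) for x in key.split(",")): float(v) for key, v in d["values"].items()
        }
        return cls(discount=d["discount"], tol=d.get("tol", 1e-4), values=values)


_TABLE_CACHE: dict[float, GittinsTable] = {}


def get_table(discount: float = 0.9) -> GittinsTable:
    """Process-wide memoized table for a given discount."""
    if discount not in _TABLE_CACHE:
        _TABLE_CACHE[discount] = GittinsTable(discount=discount)
    return _TABLE_CACHE[discount]


def gittins_policy(
    state: BeliefState, discount: float = 0.9, table: GittinsTable | None = None
) -> float:
    """Probability of moving right under the index policy: 1/0/0.5 by index order."""
    table = table if table is not None else get_table(discount)
    i_r = table.index(state.a_r, state.b_r)
    i_l = table.index(state.a_l, state.b_l)
    if i_r > i_l + 1e-9:
        return 1.0
    if i_l > i_r + 1e-9:
        return 0.0
    return 0.5
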