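"""Independent oracles used by the test suite.

These deliberately re-derive quantities by different routes than the
package (Monte-Carlo sampling, memoized finite-horizon recursion) so that
agreement is evidence of correctness rather than of shared code.
"""

from __future__ import annotations

import math
import sys
from functools import lru_cache

import numpy as np

sys.setrecursionlimit(100_000)


def mc_beta_superiority(
    a_r: float, b_r: float, a_l: float, b_l: float, n: int, rng: np.random.Generator
) -> float:
    """P(X_R > X_L) by direct Monte-Carlo sampling of the two Beta posteriors."""
    x_r = rng.beta(a_r, b_r, size=n)
    x_l = rng.beta(a_l, b_l, size=n)
    return float(np.mean(x_r > x_l))


def dp_gittins_index(a0: int, b0: int, gamma: float, tol: float = 1e-5) -> float:
    """Gittins index by bisection over a memoized finite-horizon recursion.

    The horizon T satisfies gamma**T < 1e-8; retiring at any step pays the
    candidate constant for the remaining horizon only (a genuinely
    finite-horizon formulation, unlike the package's truncated
    infinite-horizon sweep).
    """
    if gamma == 0.0:
        return a0 / (a0 + b0)
    horizon = min(max(math.ceil(math.log(1e-8) / math.log(gamma)), 1), 2000)

    def root_continuation(lam: float) -> float:
        @lru_cache(maxsize=None)
        def v(a: int, b: int) -> float:
            t = (a + b) - (a0 + b0)
            remaining = horizon - t
            if remaining <= 0:
                return 0.0
            retire = lam * (1.0 - gamma**remaining) / (1.0 - gamma)
            p = a / (a + b)
            cont = p * (1.0 + gamma * v(a + 1, b)) + (1.0 - p) * gamma * v(a, b + 1)
            return max(retire, cont)

        p = a0 / (a0 + b0)
        return p * (1.0 + gamma * v(a0 + 1, b0)) + (1.0 - p) * gamma * v(a0, b0 + 1)

    lo, hi = a0 / (a0 + b0), 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        retire_now = mid * (1.0 - gamma**horizon) / (1.0 - gamma)
        if root_continuation(mid) > retire_now:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
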