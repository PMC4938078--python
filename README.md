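# physarum-bandit

Decision-making models for the slime mould *Physarum polycephalum* solving
two-armed bandit problems.

A foraging plasmodium is offered two linear arms of 31 one-millimetre agar
sites, some blank and some carrying oat-agar food; the first site on each arm
always carries food, so exploration starts on both arms. One arm (HQ) is more
rewarding than the other (LQ), either in the number of food sites, or — in the
non-binary scenario — in total oat concentration at equal site counts. The arm
whose last site is reached first counts as "chosen". This package provides the
computational side of that experiment:

- **arena** — layouts and the twelve treatment scenarios (equal baselines,
  even/random binary layouts at 1:2 and 11:16 quality ratios, non-binary 2:1
  concentration ratio), with JSON serialization.
- **decision_models** — ten candidate policies for the probability
  P(m_t = R) of extending the right arm, conditioned on the agent's
  experience: last move direction, reward/blank counts per arm
  (A_R, A_L, B_R, B_L, each with one pseudo-observation encoding a uniform
  Beta(1, 1) prior on food density), and the leading-edge positions. They
  range from reactive rules (autocorrelation, anti-autocorrelation,
  chemotaxis) through count heuristics (most successes, highest posterior
  mean, relative successes A_R/(A_R + A_L), relative means) to fully Bayesian
  rules (most likely, probability matching on P(X_R > X_L) with
  X ~ Beta(A, B)) and the Gittins-index benchmark. A noise parameter θ mixes
  every policy with a fair coin: P = (1 − θ)·p + θ/2.
- **gittins** — Gittins indices for Beta-Bernoulli arms by the calibration
  method (bisection on the indifference payoff, value iteration over the
  count lattice), the optimal stationary-bandit benchmark.
- **simulator** — forward simulation of any policy on any treatment, plus the
  study's summary statistics: the discovery-difference curve (HQ − LQ sites
  discovered when the *i*-th site is first reached on either arm, with
  1.96 s.e. bands) and the HQ-first choice proportion with an exact binomial
  test against chance, and policy benchmarking on stationary bandits.
- **inference** — Bayesian model selection: per-model marginal likelihood of
  observed trajectories with θ integrated out against a uniform prior
  (trapezoid quadrature, log-sum-exp), and posterior model probabilities.
- **synthetic_data** — reproducible datasets with the experiment's structure
  (per-replicate random layouts, coin-flip HQ side, exclusion flags) and all
  trajectory CSV / manifest I/O.

## Worked example

```python
from physarum_bandit import (
    DatasetSpec, PolicySpec, generate_dataset, proportion_hq_first,
    first_discovery_difference, select_model, gittins_index,
)

spec = DatasetSpec(
    treatments=("4e_vs_8e",),          # 4 vs 8 evenly spaced food sites
    n_replicates=200,
    model=PolicySpec("relative_successes", theta=0.1),
    seed=42,
)
trajectories, manifest = generate_dataset(spec)

prop, pval = proportion_hq_first(trajectories)
print(f"HQ-first proportion: {prop:.3f} (exact binomial p = {pval:.2e})")

curve = first_discovery_difference(trajectories)
for rank in (2, 7, 15, 31):
    row = curve.to_frame().iloc[rank - 1]
    print(f"rank {rank:2d}: mean diff {row.mean_diff:+.2f} +/- {row.half_width:.2f}")

ranked = select_model(
    trajectories, models=("relative_successes", "most_successes", "chemotaxis")
)
for e in ranked:
    print(f"{e.model_id:20s} log evidence {e.log_marginal_likelihood:9.1f}"
          f"  posterior {e.posterior_probability:.3f}  theta_hat {e.theta_hat:.2f}")

print(f"gittins_index(1, 1, 0.9) = {gittins_index(1, 1, 0.9):.4f}")
```

prints

```
HQ-first proportion: 0.860 (exact binomial p = 1.80e-26)
rank  2: mean diff +0.03 +/- 0.14
rank  7: mean diff +0.14 +/- 0.44
rank 15: mean diff +2.28 +/- 0.76
rank 31: mean diff +10.06 +/- 1.25
relative_successes   log evidence   -6285.5  posterior 1.000  theta_hat 0.08
most_successes       log evidence   -6348.1  posterior 0.000  theta_hat 0.72
chemotaxis           log evidence   -6645.9  posterior 0.000  theta_hat 0.95
gittins_index(1, 1, 0.9) = 0.7029
```

Reading the output: 86% of simulated replicates finish the HQ arm first — a
decisive preference (the chance level is 0.5). The discovery-difference curve
hovers near zero for the first ~7 sites (balanced exploration) and then grows
steadily (exclusive exploitation of the HQ arm). Model selection on the same
data correctly identifies the generating heuristic with posterior ≈ 1 and
recovers the noise level near its true value of 0.1; θ̂ for the losing models
drifts high because noise is the only way they can explain the moves. The
Gittins index of a fresh Beta(1, 1) arm at discount 0.9 is 0.7029 — the
exploration bonus lifts it well above the myopic mean of 0.5.

## Command line

```bash
physarum-bandit arena --treatment 4e_vs_8e --out arena.json
physarum-bandit gittins -a 2 -b 3 -g 0.9
physarum-bandit simulate --treatment 4r_vs_8r --model relative-successes \
    --theta 0.1 --n 100 --seed 42 --out traj.csv
physarum-bandit synth --treatments 4e_vs_8e,4r_vs_8r --model relative-successes \
    --theta 0.1 --n 50 --seed 7 --out data/
physarum-bandit select --data data/ --models all --theta-grid 101 --out evidence.json
```

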