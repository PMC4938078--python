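# Methods

## The decision problem

An agent (a foraging plasmodium) faces two linear arms of L = 31 sites
(1 mm agar blocks). Site 1 of each arm always carries a standard 5% w/v
oat-agar food block; other sites are blank or carry food according to the
treatment. At each step the agent extends its leading edge by exactly one
site on exactly one arm; the replicate ends the first time either arm's last
site is reached, and that arm is the "choice". Exploration is therefore a
sequence of binary moves m_t ∈ {L, R}, and every behavioural model is a rule
for P(m_t = R) given past experience.

The agent's experience is summarised by six quantities: the previous move
direction, whether it was rewarded, and four counts — A_R, A_L (rewarded
sites per arm) and B_R, B_L (blank sites per arm) — each initialised at 1.
The unit offsets are pseudo-observations encoding a uniform Beta(1, 1) prior
on each arm's food density, so the posterior for arm density is
Beta(A, B) throughout. Arena initialisation consumes the guaranteed site-1
rewards: after it, A_R = A_L = 2, B_R = B_L = 1, both leading edges at
site 1.

## Treatments

Twelve named scenarios, all on 31-site arms with 5% food sites unless noted:

| name        | LQ | HQ | layout  | note |
|-------------|----|----|---------|------|
| 31_vs_31    | 31 | 31 | even    | equal baseline |
| 1_vs_1      | 1  | 1  | even    | equal baseline |
| 8e_vs_8e    | 8  | 8  | even    | equal baseline |
| 8r_vs_8r    | 8  | 8  | random  | equal baseline |
| 1_vs_8e     | 1  | 8  | even    | strongly unequal |
| 4e_vs_8e    | 4  | 8  | even    | 1:2 ratio |
| 4r_vs_8r    | 4  | 8  | random  | 1:2 ratio |
| 8e_vs_16e   | 8  | 16 | even    | 1:2, doubled counts |
| 8r_vs_16r   | 8  | 16 | random  | 1:2, doubled counts |
| 11e_vs_16e  | 11 | 16 | even    | 11:16, harder |
| 11r_vs_16r  | 11 | 16 | random  | 11:16, harder |
| nonbinary   | 8  | 8  | random  | graded magnitudes, HQ total = 2 × LQ total |

Even layouts place reward k of n at site 1 + round(k·(L−1)/(n−1)) (half-up
rounding; n = 1 keeps only site 1). This forces site 1, spans the arm, and
makes consecutive gaps differ by at most one — the maximally even
deterministic rule. Random layouts keep site 1 and draw the remaining
positions uniformly without replacement from sites 2..L; no minimum-gap
constraint is imposed. The HQ side is a fair coin per replicate.

**Non-binary magnitudes.** Both arms get 8 food sites at random positions;
magnitudes are drawn uniformly on [1%, 8%] and rescaled so the HQ
concentrations sum to `hq_total` (default 0.40, i.e. a mean site
concentration of 5%) and the LQ concentrations to half that. The 2:1 total
ratio is the binding constraint and is exact; per-site magnitudes are kept
inside [1%, 8%] by iterative clip-and-renormalise whenever the target total
is feasible for that range (n·1% ≤ total ≤ n·8%), and by a pure rescale
otherwise. The default of 0.40 was chosen because it is the unique scale at
which the graded sites are commensurate with the standard 5% reference and
the per-site range constraint is satisfiable.

## The model family

With I(·) the indicator, means μ = A/(A+B), and Q the Beta posterior:

1. **autocorrelation** — P = I(m_{t−1} = R); 0.5 before any move.
2. **anti_autocorrelation** — P = I(m_{t−1} = L); 0.5 before any move.
3. **most_successes** — P = I(A_R > A_L) + 0.5·I(A_R = A_L).
4. **highest_mean** — indicator on μ_R vs μ_L (compared by exact integer
   cross-multiplication), 0.5 at ties.
5. **relative_successes** — P = A_R/(A_R + A_L).
6. **relative_means** — P = μ_R/(μ_R + μ_L).
7. **most_likely** — indicator on P(X_R > X_L) vs 0.5, X_arm ~ Beta(A, B).
8. **probability_matching** — P = P(X_R > X_L).
9. **chemotaxis** — P = 1 if food sits at the next right site only, 0 if at
   the next left site only, 0.5 otherwise. This parameter-free form keeps
   the model-comparison fair (no extra fitted parameter); it is isolated
   behind the policy interface and can be swapped.
10. **gittins** — P = indicator on the Gittins indices of (A_R, B_R) vs
    (A_L, B_L) at a fixed discount (default 0.9, reported in all outputs).

Every policy then passes through the noise mixture
P ← (1 − θ)·P + θ/2 with θ ∈ [0, 1]: with probability θ the agent ignores
the heuristic and flips a fair coin. This is the simplest symmetric
corruption and keeps every move's likelihood ≥ θ/2 > 0, which the marginal
likelihood needs. Once an arm's last site has been reached (possible only
when replaying external data), the other arm is forced with probability one
and noise is disabled for the forced move.

**Beta superiority.** P(X_R > X_L) for independent Beta posteriors uses the
exact finite sum
P(X₁ > X₂) = Σ_{i=0}^{A₁−1} B(A₂+i, B₁+B₂) / [(B₁+i)·B(1+i, B₁)·B(A₂, B₂)]
(computed with log-gamma, memoized) for integer counts, and adaptive
quadrature of pdf_R·cdf_L (abs. tol 10⁻⁸) otherwise. Arguments are
canonically ordered so that swapping the arms yields an exactly
complementary probability and equal-count states give exactly 0.5.

**Graded rewards.** Food encounters increment A by magnitude/5% (so every
standard binary site contributes exactly 1, leaving all binary treatments
untouched), which lets count-based models weight reward magnitude in the
non-binary scenario — without magnitude sensitivity no count-based model
could distinguish two arms with equal site counts. A `graded=False` switch
restores strict binary increments. Note that with fractional increments the
identity A + B − 2 = sites discovered holds only for binary arenas.

## Gittins indices

The index of a Beta(A, B) Bernoulli arm under geometric discount γ is the
constant payoff λ* making retirement (value λ*/(1−γ)) indifferent to pulling
the arm once and continuing optimally. `gittins_index` bisects on λ
(default tolerance 10⁻⁴ on λ), evaluating the continuation value by backward
induction over the count lattice truncated at the smallest horizon T with
γ^T < 10⁻⁸ (hard cap 2000); beyond T states take the myopic bound
max(λ, μ)/(1−γ), so the truncation error is below the bisection tolerance.
At γ = 0 the index is the posterior mean exactly, and the index policy
reduces to highest_mean.

For simulations needing thousands of states, `GittinsTable.bulk_fill`
computes a whole lattice in one pass: a single backward induction vectorised
over an 801-point λ grid yields the continue-minus-retire gap for every
state; the gap is piecewise linear in λ, so its root — the index — is
recovered by local linear interpolation (observed agreement with per-state
bisection: ~10⁻⁴, worst ~3×10⁻⁴ near index 1). Tables are memoized per
discount and serializable to JSON.

## Simulation and summary statistics

Trajectories are simulated one site per step from the post-initialisation
state, with the direction drawn from the noise-mixed policy, until one arm's
last site is reached; trajectory length is therefore between L−1 and
2(L−1) moves. All randomness flows through numpy Generators seeded per
replicate, so datasets are bitwise reproducible.

**Discovery-difference curve.** For rank i = 1..L, the difference
(HQ sites discovered) − (LQ sites discovered) is recorded at the moment the
i-th site is first reached on either arm (rank = the leading edge maximum,
which increases by at most one per move). The curve reports the mean across
replicates and a 1.96 s.e. band (ranks with fewer than two contributing
replicates get a zero-width band). Replicates that terminate before rank i
carry their final difference forward by default; a drop-out mode excludes
them instead — the aggregation choice for unequal-length replicates is
genuinely open, and carry-forward was chosen so late ranks keep the full
cohort. Since a replicate ends only when rank L is reached, the two modes
differ only for externally truncated data.

**Choice proportion.** The fraction of (non-excluded) replicates whose HQ
arm finished first, with a two-sided exact binomial test against 0.5
(scipy's `binomtest`, conventional point-mass handling: 15/30 gives p = 1).
Equal-arm treatments have no HQ and are rejected.

**Stationary-bandit benchmark.** `compare_performance` runs each policy on a
two-armed Bernoulli bandit with fixed success probabilities and no arm
exhaustion, reporting mean cumulative reward ± Monte-Carlo s.e. This
isolates exploration/exploitation quality from arena geometry; the Gittins
policy is the optimal-performance reference.

## Model selection

The likelihood of a trajectory under (model, θ) is the product over realized
moves of the noise-mixed model probability of that move (forced moves
contribute 1). Because the mixture is affine in θ, each model's noise-free
move probabilities are computed once per trajectory and the θ dependence is
vectorised. The evidence integrates the pooled log-likelihood over θ with a
uniform prior on [0, 1] — trapezoid rule on an evenly spaced grid (default
101 points; refining to 201 changes pooled evidences by < 10⁻⁴ relative),
combined in log space. One global θ is shared across treatments per model; a
per-treatment fit is possible by calling `marginal_loglik` on subsets. The
Gittins model enters with its discount fixed (default 0.9) rather than
integrated — it is a benchmark, not a fitted competitor. Posterior model
probabilities use a uniform prior over the supplied model set; ties are
broken lexicographically.

Model-recovery checks use the set of eight mutually distinguishable
non-Gittins models: `most_likely` is excluded because it agrees with
`highest_mean` on almost all count states reachable in these arenas, so the
pair cannot be told apart at realistic sample sizes.

## Synthetic data

The generator emulates the experiment's statistical structure: tens of
replicates per treatment (the study ran up to 36 concurrently), fresh random
layouts per replicate for random/non-binary treatments, a fair-coin HQ side,
termination at the first arm end, and an exclusion flag emulating discarded
replicates (default rate 0 — the real rate is unknown). Excluded replicates
stay in the files, flagged, and analysis stages skip them. Steps are
ordinal: the 10-minute photographic cadence of the experiment is not
modelled because every model is defined per move, not per minute. What the
generator does **not** emulate: simultaneous extension on both arms within
one timestep (observed in a small minority of experimental timesteps; the
model grammar is one move per step), cells leaving the arms, biomass and
tubule morphology, and chemical diffusion of food cues. Tests passing on
synthetic data therefore validate the algorithmic pipeline, not those
biological effects.

## Problem sizes and defaults

- Choice-proportion and curve computations: 2000 replicates per treatment,
  generating model relative_successes at θ = 0.1 (the heuristic and noise
  scale that best describe the organism).
- Model selection: ~100 replicates pooled over three treatments
  (4e_vs_8e, 4r_vs_8r, 1_vs_8e), θ grid 101; recovery checks use 5 datasets
  per generating model.
- Bandit benchmark: success probabilities (0.3, 0.6), 100 steps, 2000
  simulations.
- Gittins: discount 0.9, bisection tol 10⁻⁴, truncation 10⁻⁸.

## Known limitations

- The chemotaxis rule and the noise construction are the package's own
  minimal formalisations (parameter-free attraction; fair-coin corruption);
  both sit behind the policy interface so alternatives can be swapped in.
- The evidence quadrature assumes a uniform θ prior; no analytic or MCMC
  alternative is provided (the 1-D integral does not need one).
- Bulk Gittins tables trade ~10⁻⁴ index accuracy for a ~100× speedup; use
  `gittins_index` directly where full bisection accuracy matters.
- Experimental point estimates (per-treatment proportions measured on living
  cells, exploration lengths) are properties of the organism, not of the
  models, and are not reproduced — only the qualitative patterns the models
  predict are.
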