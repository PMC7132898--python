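# Methods

This note records the models, statistical conventions and numerical choices
behind `nphtest`, and what the simulation defaults do and do not represent.

## Counting-process core

All rank tests reduce a two-arm dataset to the risk table: at each distinct
event time t₁ < … < t_r, the total and research-arm numbers at risk (nⱼ,
n₁ⱼ) and events (dⱼ, d₁ⱼ). Conventions:

- **Ties.** Events tied at one time are pooled into one row; censorings tied
  with an event time remain in the risk set at that time (censoring ordered
  after events). Times are exact reals; nothing is binned.
- **Kaplan–Meier.** Product-limit estimate with explicit left limits
  S(t−0); S_min is the minimum left limit over event times. Weighted
  logrank weights always use the **pooled**-sample KM left limit, the
  standard Fleming–Harrington construction (arm-specific weights would
  break the null exchangeability of the weight process).
- **RMST.** Area under the KM step function on [0, t*], with the
  Greenwood-type variance Var = Σ_{tⱼ≤t*} Aⱼ² dⱼ/(nⱼ(nⱼ−dⱼ)),
  Aⱼ = ∫_{tⱼ}^{t*} S(u)du. Steps whose risk set is exhausted by events
  (nⱼ = dⱼ) contribute zero variance. t* beyond the observed follow-up of
  the scope is an error in the scalar API; inside the permutation engine an
  arm's curve is extended flat beyond its last observation (the relabeled
  arms' follow-up varies and the statistic must stay defined).

## The nine tests

**Weighted logrank engine.** U = Σ wⱼ(d₁ⱼ − dⱼn₁ⱼ/nⱼ),
V = Σ wⱼ² · dⱼ(nⱼ−dⱼ)n₁ⱼn₀ⱼ/(nⱼ²(nⱼ−1)) (the nⱼ = 1 term is zero),
Z = U/√V against N(0,1). Weights: 1 (`lr`), S(t−0) (`lre`), 1 − S(t−0)
(`lrl`), and for the modified versatile test
w = max{0.001, [S(t−0) − S_min]/(1 − S_min)}. The rescaling matters with a
low event rate, where S(t−0) never drops far below 1 and plain early
weights have too little contrast to distinguish themselves from the
logrank. When every left limit equals 1 (a single distinct event time) the
rescaled weight is taken as 1 by continuity.

**Supremum logrank.** The partial-sum process U(t_k) of logrank increments,
standardized by the total variance, with statistic b = max_k |U(t_k)|/√V.
The null reference is the supremum of |Brownian motion| on [0,1],
P(sup|B| ≥ b) = 4Σ_{k≥0}(−1)^k[1 − Φ((2k+1)b)], truncated at terms
< 1e−12. Standardizing by total information only (rather than rescaling
each partial sum to its own variance, a Brownian-bridge-like alternative)
makes the discrete-time supremum stochastically smaller than the continuous
one, so the test is mildly conservative — empirically ≈ 4.4% at nominal 5%
— which matches its published behaviour.

**Joint test.** Cox score χ² for the arm indicator (Breslow ties; the score
test is asymptotically the logrank, a likelihood-ratio variant is
available) plus the Grambsch–Therneau non-PH statistic
T = [Σ(g_k−ḡ)r_k]²/(V̄·Σ(g_k−ḡ)²), with r_k the per-event Schoenfeld
residuals, V̄ the mean per-event information at β̂ and g_k a transform of
the event time (identity by default; km and rank offered — the reference
implementations differ on this and identity keeps the statistic
interpretable on the natural time scale). The sum is referred to χ²(2),
using the asymptotic independence of the two components under PH.

**Combined / weighted combined.** Statistic
M = max(χ²_component, max_{t*∈grid} z²_RMST(t*)), where z_RMST(t*)
standardizes the between-arm RMST difference by the sum of the Greenwood
variances. The component is the Cox score χ² (`combined`) or the FH(0,1)
χ² (`wc`). The null is the joint permutation distribution of M under arm
relabeling, with p = (1 + #{M_perm ≥ M_obs})/(B + 1); B defaults to 1000
(500 inside simulation studies). This construction was chosen over
referring components to their asymptotic distributions because it keeps
the finite-sample size exact under exchangeability — the one property a
composite test must not lose. Consequence: the small-sample size inflation
that asymptotic composite tests exhibit (≈ 6% at fewer than ~100 events)
does not occur here; the test holds ≈ 5% at all sample sizes, bounded by
⌊0.05(B+1)⌋/(B+1). The default grid is the {0.25, 0.5, 0.75, 1} quantiles
of the pooled event times, clipped to the shorter arm's follow-up —
"a small predefined set" is all the construction needs, and quantiles
adapt it to the observed time scale. Exhaustive enumeration of label
assignments replaces random permutations on request (small n).

**Versatile tests.** z_max = max(|Z₁|,|Z₂|,|Z₃|) over the logrank, an
early-weighted (FH(1,0) for `vwlr`, rescaled for `vwlr2`) and the FH(0,1)
statistic. Correlations are estimated as
ρ_ab = Σ w_a w_b v / √(Σ w_a² v · Σ w_b² v) and the p-value is
1 − P(|N| ≤ z_max box) for a trivariate normal with that correlation
matrix.

### Numerical evaluation of the trivariate box probability

General-purpose quasi-Monte-Carlo MVN integrators proved too slow (hundreds
of ms) and not bit-reproducible for per-replicate use, so the box
probability is computed in closed form: Owen's T function gives the
bivariate CDF; the trivariate case conditions on the first component and
integrates the conditional bivariate box with 96-node Gauss–Legendre
quadrature (absolute error ≈ 1e−7, validated against large-sample Monte
Carlo). Components correlated at |ρ| ≥ 1 − 1e−9 with another are redundant
inside a symmetric box and are dropped first — this is the practically
important case: under a low event rate the FH(1,0) weights barely vary, and
corr(Z_lr, Z_lre) ≈ 0.9996.

## Simulator

Control arm: cumulative hazard H₀ from exponential, Weibull, log-logistic
or restricted-cubic-spline (log H₀ vs log t, user-supplied coefficients;
monotonicity validated at construction — the package evaluates spline
models, it does not fit them). Research arm: H₁(t) = hr_b·H₀(t) for
t ≤ t*, hr_b·H₀(t*) + hr_a·(H₀(t) − H₀(t*)) after, i.e. a step hazard
ratio continuous in H₁. Event times by inversion of H against −log U
(closed form where available, otherwise bracketed Brent to 1e−10 relative
tolerance). Censoring is uniform on [low, high] — staggered uniform accrual
with an administrative horizon — independent of arm and event times.

Presets define the study conditions:

- **low event rate**: exponential with S₀(5y) = 0.9, censoring U[3,5];
- **high event rate**: Weibull (shape 1.3, mildly increasing hazard — a
  plausible shape for an advanced-disease population) with S₀(3y) = 0.1,
  censoring U[2,3];
- step HRs per scenario cell: early 0.3→1 (low) / 0.5→1 (high), late
  1→0.3 (low) / 1→0.5 (high); PH uses HR 0.75.

These parametric stand-ins reproduce the features that drive rank-test
behaviour — the event rate, the censoring pattern, and the location of the
change point on the information-fraction scale. They do **not** reproduce
any particular trial's hazard shape; absolute power numbers therefore
transfer only qualitatively, while empirical sizes are essentially
distribution-free. Green tests here say the machinery is correct and the
qualitative power orderings hold under these conditions, not that a given
real trial would see the same power.

## Design module

Required events e = ⌈4(z_{1−α/2} + z_power)²/(ln hr)²⌉ (Schoenfeld, 1:1
allocation). For step-HR effects the formula is applied to the
event-weighted average log HR; the initial n = e/P(event) is then adjusted
by simulated logrank power (normal-approximation rescaling, then local
steps) until within 1 percentage point of target — the package's stand-in
for external sample-size software, sufficient because sample size only pegs
the logrank benchmark. The information fraction is
IF(t*) = ∫₀^{t*} f₀S_C / ∫₀^∞ f₀S_C over observed control-arm events
(censoring-adjusted), computed by quadrature; its inverse (for placing
change points at target IFs) by Brent root-finding to |ΔIF| ≤ 1e−4.

## Study driver

Per scenario, replicate trials are simulated and every requested test run
once; rejection rates come with Clopper–Pearson 95% CIs and the mean
observed control-arm IF. Each replicate uses a deterministically derived
child seed, so results are reproducible and independent of execution
order. A scenario where any test errors on > 1% of replicates aborts as
degenerate. Deficits: per-scenario benchmark = best test's power; a test's
deficit is benchmark − power, averaged per effect type; mean deficit
< 0.05 across event rates flags a test acceptable; late-effect scenarios
with t* = 0 are proportional hazards and are summarized separately.

Default scale: 1000 replicates per scenario and B = 500 permutations inside
studies (5000/1000 restorable by flags). The acceptance script pools 5000
identical-arm replicates over sample sizes {1400, 2200, 3400} (low rate,
>100 expected events each) for sizes, and {60, 80, 110} (high rate, ≤100
events) for the small-sample check — scales at which binomial error
(±0.3–0.4 pp) is small against the effects of interest.

## Known limitations

- Only two arms, 1:1 allocation, right censoring; no stratification,
  left truncation or competing risks.
- Step hazard ratios with a single change point cover early/late/PH
  patterns only; crossing-hazards generators are out of scope.
- The combined/weighted-combined permutation construction is size-exact
  but not identical to asymptotic composite variants, whose small-sample
  inflation it deliberately avoids; their p-values differ in finite
  samples.
- Spline control distributions are evaluated, not fitted.
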