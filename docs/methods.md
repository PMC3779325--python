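# Methods

`bathyrad` implements the quantitative machinery behind a macroevolutionary
analysis of chemosymbiotic deep-sea mussels (Bathymodiolinae and relatives):
diversification-rate models on a time-calibrated phylogeny, a mass-extinction
hypothesis test, state-dependent speciation (BiSSE), ancestral-state
reconstruction, a phylogenetic comparative test battery, nonparametric
rate-smoothing (NPRS) dating, and a synthetic tree/trait generator that
emulates the study system so every stage can be exercised without the
empirical data.  This note records the models, the numerical choices, and
what the synthetic experiments do and do not demonstrate.

## Reconstructed-process likelihoods

All diversification models are likelihoods of the *branching times* of an
ultrametric tree — the ages `t_2 > … > t_{n-1}` of its internal nodes, with
the crown age `t_1 = T` conditioned upon rather than treated as an event.
Writing `N(t)` for the lineages-through-time step function and `E(t)` for the
probability that a single lineage alive at age `t` leaves no sampled
descendant at the present, the log-likelihood is the inhomogeneous-Poisson
form

```
lnL = Σ_j ln[ N(t_j) λ(t_j) (1 − E(t_j)) ]  −  ∫_0^T N(t) λ(t) (1 − E(t)) dt .
```

We verified algebraically (and pin with ODE/quadrature oracle tests) that
this equals the branch-product D/E likelihood conditioned on the crown age
and on both crown lineages surviving, *including* in the presence of
instantaneous mass-extinction events: an event at age `t_ME` with survival
fraction ρ enters only through the multiplicative jump
`1 − E(t⁺) = ρ (1 − E(t⁻))`, and the per-lineage ρ factors for reconstructed
lineages crossing the event fall out of the identity automatically.  Between
events `E` satisfies a constant-coefficient Riccati equation with closed-form
solution, so the likelihood is evaluated piecewise-analytically — no ODE
solver in the hot path.

The model set: constant pure birth; constant birth–death parameterized by
net rate `r = λ − μ` and extinction fraction `a = μ/λ`; density-dependent
logistic `λ(N) = r1 (1 − N/k)` and exponential `λ(N) = r1 N^(−x)` speciation
(the sign convention makes a printed negative `x` a rate *increasing* with
standing diversity); piecewise-constant Yule models with one or two shift
ages; and a Weibull-shaped rate trend `λ(t) = (β/η)(t/η)^(β−1)` in age `t`
inside an analysis window, which reduces to a constant rate at `β = 1` and
is compared to it by a 1-d.f. likelihood-ratio test.

### Multi-rate Yule profile

For fixed shift ages the per-segment rate MLEs are `events / lineage-time`,
so fitting reduces to a profile over shift ages.  Two structural facts shape
the implementation:

* with the event-to-segment assignment held fixed, the profile
  log-likelihood is **convex** in the lineage-time split, so its maximum over
  a continuous shift age is attained at a branching time;
* for the two-shift model an unrestricted shift age is degenerate — letting a
  segment collapse onto a single branching event drives the likelihood to
  +∞, the same pathology as a variance collapsing in a Gaussian mixture.

Shift ages are therefore restricted to the observed branching times (an
event tied with a shift age belongs to the older segment), enumerated
exhaustively and vectorized (all ~n²/2 two-shift candidates at once).  A
test cross-checks the enumeration against a naive loop with trapezoid
lineage-time integration.

### Model selection and the shift test

`AIC = −2 lnL + 2k` is reported for the model table; the simulation-based
shift test uses AICc by default (with `n_obs` = number of branching times),
because the profiled shift models effectively spend their parameters
searching many candidate configurations and plain AIC prefers them spuriously
on constant-rate data (measured: the 3-rate model "wins" ~50% of constant-rate
replicates under AIC but pure birth wins a clear majority under AICc).  The
test statistic is `IC(best rate-constant) − IC(best rate-variable)`; its null
distribution comes from trees simulated at the pure-birth MLE conditioned on
the observed crown age and tip count, with the add-one p-value
`(1 + #{null ≥ obs}) / (1 + R)`.  Incomplete sampling scenarios simulate the
inflated true richness `round(n/(1−f))` and prune uniformly back to `n`.

A caveat the simulations make explicit: at the burst magnitude actually
fitted to the mussel tree (0.01 / 0.17 / 0.05 events/Myr, 41.2 and 33.8 Ma
shifts, 62 tips), the *average* power of the test against its own simulated
null is modest (~15% at α = 0.05), because simulation truths taken from
fitted values inherit winner's-curse attenuation and the exhaustive profile
produces a relatively heavy null.  An observed statistic the size of the
empirical one (2ΔlnL ≈ 19–20) still falls in the null's far tail.  Tests
therefore assert high power at a stronger burst (0.8/Myr) plus stochastic
inflation of the statistic at the preset magnitude, not the unattainable
80% at the preset itself.

## Mass-extinction test

H0 is constant-rate birth–death; H1 adds an event at a fixed age (default
57 Ma) with fixed survival ρ (default 0.05), so both hypotheses have the
same two free parameters `(λ, μ)` and the statistic `ΔlnL = lnL₁ − lnL₀` is
referred purely to simulation.  Trees are simulated under each fitted
hypothesis conditioned on the observed root age and tip count; the test
reports both ΔlnL distributions, H0's 5% rejection level, pointwise 95% LTT
envelopes, and the add-one p-value.

Conditioned simulation is exact, not rejection-based: conditional on
`(T, n)`, the `n − 2` post-crown branching ages are iid with CDF
`(1 − e^{−A(t)}) / (1 − e^{−A(T)})` where `A(t) = ∫_0^t λ(1 − E)`, and `A`
inverts in closed form inside each inter-event segment.  The same
factorization (for pure birth, `A(t) = Λ(t)`) powers the Yule-family
conditioned sampler used by the shift test and the synthetic preset.  Both
samplers are validated against forward Gillespie simulation with rejection
by two-sample KS tests.

Calibration note: the parametric bootstrap is exchangeable (measured type-I
error within the binomial band at α = 0.05) when the observed tree is a
typical draw of its generating process.  Feeding the test a tree whose tip
count is wildly atypical for its own fitted parameters degrades calibration,
because the crown-conditioned likelihood also uses the information in `n`.

## State-dependent speciation

The BiSSE likelihood integrates the standard coupled E/D equations backward
in age, multiplies D elementwise by the state's λ at every internal node
(root included), and combines root states either with FitzJohn weights
(default) or equally.  State-specific sampling fractions enter the tip
conditions (`D_i = ρ_i`, `E_i(0) = 1 − ρ_i`); missing tip states are
ambiguous (`D = (ρ0, ρ1)`).  Because `E(t)` is branch-independent, the D
system is a shared linear time-varying ODE: its 2×2 fundamental matrix is
integrated once per parameter vector and branches are propagated by 2×2
solves; with `μ = 0` and complete sampling `E ≡ 0` and propagation is a
single diagonalized matrix exponential, vectorized over branches.  Oracle
tests pin the likelihood against a monolithic high-tolerance ODE solve and
against the exact factorization `BiSSE = Yule tree density × Mk likelihood`
when rates are state-independent.

The hypothesis pair mirrors the symbiont analyses: H0 is a Yule-constrained
model with `λ0 = λ1` and free transition rates (3 parameters), H1 frees
`λ0 ≠ λ1` (4 parameters), giving a 1-d.f. χ² LRT.  Extinction is fixed at 0
in both (full BiSSE remains available through `bisse_loglik`).

## Comparative battery

* **Mk ASR** — equal-rates (default) or all-rates-different rate matrix fitted
  by ML, marginal node probabilities by a two-pass (inside/outside) algorithm
  with per-node rescaling, flat root prior; multistate/ambiguous tips carry
  partial likelihood 1 on each occupied state.  Exhaustive-enumeration
  oracles pin both the likelihood and the marginals.
* **Brownian ASR** — GLS ancestral means and conditional variances under the
  shared-path-length covariance; σ² by ML; shell lengths are natural-logged
  (mm) before analysis.
* **Depth discretization** — half-open 500-m bins `[0,500), [500,1000), …`
  reported 1-based; a range maximum on a bin boundary closes the bin below;
  a species' range yields the set of intersected bins (multistate character).
* **Pagel's test** — 4-rate independent vs 8-rate dependent joint chain for
  two binary characters; the independent likelihood factorizes into two
  closed-form 2-state prunings; the dependent model is optimized with
  restarts (default 10, mirroring the study's iterations) over bounded log
  rates; the Monte-Carlo p refits both models to data simulated under the
  fitted independent model.  The joint-chain pruning is JIT-compiled
  (numba) with a pure-Python fallback.
* **Phylogenetic ANOVA** — ordinary one-way F, with the null F distribution
  from Brownian data simulated on the tree (σ² estimated from the data; F is
  scale-invariant so this choice is cosmetic) alongside the parametric p.
* **PGLS** — GLS regression with Brownian covariance via statsmodels;
  intercept/slope t statistics, overall F, and *residual* degrees of freedom
  (`n − 2`) are reported.
* **Mann–Whitney** — exact two-sided p for groups of ≤ 12 without ties,
  tie-corrected normal approximation otherwise.

Habitat can be analyzed with vent and seep distinct or pooled into one
chemosynthetic category (`pooled_habitat`), matching both codings used in
the study system.

## NPRS dating and calibrations

NPRS minimizes the sum over ancestor–descendant branch pairs of squared
local-rate differences (rate = substitutions / duration), with the variance
of the root children's rates as the root term.  Node ages are parameterized
as logistic fractions of the feasible interval below the parent, so the
ordering constraint holds structurally; constraint minima propagate up and
maxima down before optimization (L-BFGS-B, 10 jittered restarts by default).
The root age must be bounded by a constraint.  Zero-length branches get a
1e-9 Myr duration floor.

Fossil calibrations are offset-exponential priors; the *soft maximum* is
defined as the 0.95 quantile, `offset − mean · ln 0.05`, which reproduces
the Middle Eocene (45 + 1.2 → 48.6 Myr) and Late Oligocene (25.2 + 0.7 →
27.3 Myr) bounds exactly.  The Middle Miocene calibration (15.1 + 1.3 Myr)
is *not* consistent with this rule (0.95 quantile 19.0 Myr, declared bound
15.9 Myr); the package reports computed bounds next to declared ones rather
than silently reconciling them.

## Synthetic data

The mussel-like preset is the generator's reference condition: crown age
85 Myr, episodic pure-birth rates 0.01 / 0.17 / 0.05 events/Myr with shifts
at 41.2 and 33.8 Ma, 62 extant species — the magnitudes estimated for the
radiation.  Trait generators produce a 3-state habitat character evolving
from an organic-fall ancestor, rare-gain binary symbiont characters,
Brownian ln-shell-length with a vent/seep size increment, and 500-m-scale
depth ranges with vent/seep species deeper on average; ~15% of optional
entries are blanked to emulate incomplete trait knowledge.

What the generator does *not* emulate: phylogenetic uncertainty (a single
true tree, no posterior distribution), gene-tree conflict, fossil tips,
diversified or geographically structured sampling, correlated evolution
between shell size and depth beyond the habitat linkage, and
measurement error in traits.  Passing recovery/calibration tests therefore
demonstrates correctness of the estimators under the stated models, not
robustness to the violations real data bring.

## Problem sizes and tolerances

Monte-Carlo test suites run at reduced sizes chosen to keep the default
`pytest` run around ten minutes on one CPU: type-I calibrations use
100 outer × 99 inner replicates (shift test), 24 × 59 (mass-extinction),
24 × 19 (Pagel), 100 × 199 (ANOVA) and 150 single fits (PGLS), with inner
counts chosen so that `α (R + 1)` is an integer (exact Monte-Carlo size) and
acceptance bands computed as binomial 95% intervals at the sizes actually
run.  Recovery suites: 500 Yule trees (rate), 100 preset trees (shift ages),
12 BiSSE trees of 60–250 tips (rate ordering), 200 Brownian replicates (σ²).
Oracle tolerances: 1e-6 (diversification and mass-extinction likelihoods vs
quadrature), 1e-5 (BiSSE vs ODE oracle and factorization), 1e-8 (Mk vs
enumeration).  Optimizers: Nelder-Mead on log/logit-transformed parameters
with restarts for the multimodal fits; L-BFGS-B for the smooth birth–death
surfaces (verified against Nelder-Mead optima to ~1e-13).

All simulators take a seed or a `numpy` Generator and are bit-reproducible;
conditioned quantities are exact (crown age to machine precision, tip counts
exactly).
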