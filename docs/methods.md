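# Methods

## Model

The population is a two-type Bienaymé–Galton–Watson process in a random
environment. Type 1 individuals are *active*, type 2 *dormant*; dormant
individuals are constrained to wake `(1,0)`, persist `(0,1)`, or die
`(0,0)` — no other transitions. The environment `(Iₙ)` is a stationary
two-state Markov chain on {1 = healthy, 2 = harsh} with switching
probabilities `s1` (1→2) and `s2` (2→1), started from its stationary
law `π = (s2, s1)/(s1+s2)`. `s1, s2 ∈ (0,1]` with `s1·s2 < 1` keeps the
chain ergodic; deterministic alternation (`s1 = s2 = 1`) is rejected by
validation and reachable only as a limit.

Conditionally on the environment, the expected population evolves by
the matrix product `E[Zₙ] = Z₀ · M(E₁) ⋯ M(Eₙ)`, so long-run fitness is
the maximal Lyapunov exponent
`φ = lim (1/n) log ‖M(E₁) ⋯ M(Eₙ)‖`. By the classification of
multi-type branching processes in random environments, `φ < 0` forces
almost-sure extinction and `φ > 0` permits survival with positive
probability; `φ` is also the almost-sure growth rate of the population
conditioned on survival. All exponents are natural-log per generation.
`log 0 = −∞` propagates as a value (a strategy certain to die has
`φ = −∞`), never as an exception.

## Exact exponents (rank-1 strategies)

When both mean matrices have rank one, `M(e) = ℓ(e) r(e)ᵀ`, the product
telescopes through the scalars `⟨r(Iₖ), ℓ(Iₖ₊₁)⟩` and Birkhoff's
theorem gives the closed form implemented in `lyapunov_rank1`
(equivalently in trace form; see the README). The classic strategies
are specializations:

* responsive switcher `M(1) = [[m¹,0],[1−d¹,0]]`,
  `M(2) = [[0,m²],[0,1−d²]]`;
* preliminary switcher — the mirror image;
* stochastic switcher with `det M(e) = 0`, i.e. dormant row
  proportional to the active one (`1−wᵉ−dᵉ = wᵉ·m_d/m_a`);
* the dormancy-free benchmark, embedded as the reducible pair
  `M(e) = [[mᵉ,0],[1−dᵉ,0]]` and always routed to the scalar rule
  `φ = E_π[log m(I₀)]`, never through Perron–Frobenius-dependent code.

The specialized formulas are cross-checked against the generic trace
formula to 1e−12 on 1000 random parameter draws, and against the
Monte-Carlo estimator within 3 standard errors.

`perron_root` is kept separate and **unlogged**: in a constant
environment the natural fitness summary is the growth *factor* ϱ(M)
per generation. For the binary dormancy parameter set
`(p, ε, b, w, d) = (4/5, 0, 2/5, 1/2, 1/25)` the mean matrix is
`[[0.64, 0.48], [0.50, 0.46]]` and its Perron root computes to
1.0481 (some sources quote ≈ 1.050 for this matrix; the quadratic
eigenvalue formula gives 1.04810, which is what the package reports).

## Bounds (rank-2 strategies)

No closed form exists for general rank-2 pairs. Every bound is built on
the rank-≤2 factorization `M = ℓ¹r¹ᵀ + ℓ²r²ᵀ` and the transfer matrices
`A(i,j)ᵃᵇ = ⟨rᵃ(i), ℓᵇ(j)⟩`, whose products have the same exponent as
the `M`-products (verified against Monte-Carlo for every factorization
flavor). Four flavors are provided: by rows, by columns, and the two
determinant-signed splittings (valid for `det ≥ 0` resp. `≤ 0`;
`flavor="auto"` picks by sign). The rows flavor yields `A(i,j) = M(i)`
and the columns flavor `A(i,j) = M(j)`; the two differ only by an index
shift of the product, so the exponent is unaffected, but the spectral
and retrospective presets are derived for `A(i,j) = M(i)` and therefore
default to rows.

* **Spectral upper bound** (Jensen): for positive scalings λ(i,j),
  `φ ≤ E[log λ] + log ϱ(Â*)` with `Â*` the 4×4 environment-blocked
  matrix of scaled A's. Presets: λ ≡ 1 and λ(i,·) = ϱ(M(i)) (the
  eigenvalue-scaled variant). No optimization rule over λ is known;
  only the presets are offered.
* **Variational (entropy) lower bound**: an auxiliary {1,2}-valued
  chain with free parameters `μ_ijy ∈ [0,1]` induces a 4×4 chain `Q` on
  (environment, type); whenever `Q` is ergodic,
  `φ ≥ Σ q_iy Q^{iy,jz} (log A(i,j)^{yz} + h(μ_ijy))` with `h` the
  binary entropy. `optimize_lower_bound_markov` maximizes over uniform
  random μ-draws (non-ergodic draws skipped) plus the retrospective
  candidate below; under a fixed seed the draw sequence is nested, so
  the result is monotone in the number of draws. A zero A-entry carried
  with positive weight short-circuits to a valid −∞ bound.
* **Retrospective-chain bound** (`hl_lower_bound`): choosing
  `μ_ijy = Θ(i)_y1` with
  `Θ(e) = diag(v(e))⁻¹ (M(e)/ϱ(e)) diag(v(e))` — `v(e)` the positive
  right Perron eigenvector — gives the eigenvector form
  `φ ≥ E_π[log ϱ(I₀)] + q (I₄ − blockdiag(Θ(1),Θ(2))) log v`. The two
  routes are verified identical to 1e−9. `v(e)` is ℓ¹-normalized; the
  correction term is invariant to a common rescaling, so the
  normalization is a recorded convention, not a modelling choice.
  Requires irreducible matrices, certified by positive off-diagonals
  (positivity of the computed eigenvector is not sufficient: reducible
  pairs can have strictly positive eigenvectors).
* **Trace-determinant bound** for stochastic switchers with
  environment-independent dormant row:
  `φ ≥ E[log(tr M(I₀) − max{det M(1)/m_a, 0})]`; at `det M(1) = 0` it
  collapses to the exact zero-determinant formula.
* **Norm bounds**: one-step sub/super-multiplicative bounds
  `E_π[log f(M)] ≤ φ ≤ E_π[log ‖M‖]` with f ∈ {permanent, min row/col
  sum, diagonal entry}, and the improved upper bound
  `φ ≤ E_π[log‖M‖] + Ψ`, `Ψ = s₁s₂/(s₁+s₂) ·
  log(min{‖M(1)M(2)‖, ‖M(2)M(1)‖}/(‖M(1)‖‖M(2)‖)) ≤ 0`. For strongly
  active-leaning pairs at very small harshness (α ≲ 0.002 in the fast
  regime) the improved ℓ¹ bound undercuts the eigenvalue-scaled
  spectral bound.

The default matrix norm everywhere is the entrywise absolute sum
`‖B‖ = Σ|Bⁱʲ|`: it is sub-multiplicative, makes the finite-path Gibbs
variational principle *exact* (the entropy-penalized supremum over
type-path densities equals the log norm of the realized A-product,
brute-force-checked up to path length 12), and the exponent is
norm-independent anyway.

## Stochastic and enumeration estimators

`mc_lyapunov` multiplies mean matrices along simulated stationary
environment paths, renormalizing the running 2×2 product by its entry
sum each step and accumulating the log scale, so products of length
10⁵ neither overflow nor underflow; replicates run in lock-step with
vectorized arithmetic and the replicate mean and standard error are
reported. It is the package's independent oracle: every closed form and
every bound is tested against it at 3-standard-error tolerance.

`sandwich_bounds` computes the exact k-step expectations
`φ̲ₖ = (1/k)E[log f(M₁⋯Mₖ)]` (super-multiplicative f, default the
permanent) and `φ̄ₖ = (1/k)E[log ‖M₁⋯Mₖ‖]` by depth-first enumeration of
all 2ᵏ environment paths with shared prefix products (k ≤ 16). The
lower sequence increases and the upper decreases to φ — a monotonicity
the tests check exactly, not statistically. Note the degenerate case:
strategies whose matrices carry a zero column (responsive,
preliminary, sleepless) annihilate every super-multiplicative
functional, so their lower sequence is identically −∞; the upper
sequence still converges.

## Individual-based model and extinction analytics

The binary dormancy model is a caricature of fission/sporulation: an
active cell dies w.p. `1−p+ε`, splits w.p. `(p−ε)b`, sporulates w.p.
`(p−ε)(1−b)`; a dormant cell wakes w.p. `w`, dies w.p. `d`, persists
otherwise. `ε ∈ [0, p)` is the trade-off carried by the trait; `b = 1,
ε = 0` recovers the 1-type splitting benchmark `p δ₂ + (1−p) δ₀` in
distribution.

Constant-environment quantities come from the joint probability
generating functions: extinction probabilities as the minimal fixed
point of `s ↦ f(s)` iterated from `(0,0)` (tolerance 1e−12, up to 10⁶
iterations — convergence is linear and slow near criticality), the
survival curve `P[T > n] = 1 − f⁽ⁿ⁾(0)` by n-fold composition, and
`E[T] = Σ P[T > n]` truncated at a cap with a decay classifier: if the
tail at the cap still exceeds tolerance, the last-decade ratio decides
between a geometric remainder (summed) and sub-1/n decay (declared
+∞ — the critical rate `P[T>n] ≍ c/n` is non-summable and yields a
last-decade ratio ≈ 0.1, cleanly separated from geometric decay by the
0.05 threshold). Extinction time counts from generation 1
(`T = inf{n ≥ 1 : Zₙ = 0}`).

Closed forms for the supercritical survival probabilities
(`σ_X = 2 − 1/p`; for ε = 0,
`σ_Z = 2 − 1/(bp) + ((1−b)/b)·w/(w+d)`, clamped to [0,1]) agree with
the pgf route to 1e−9 on random supercritical parameter sets.

The simulator draws exact multinomial offspring per parent type and
generation, vectorized across replicates (`simulate_survival`) or as a
single exact trajectory (`simulate_population`). Populations exceeding
a cap are flagged (batch mode freezes them and counts them as
survivors — at the default cap of 10⁴ individuals extinction within the
simulated horizons is no longer a practical possibility). A helper
realizes any mean-matrix strategy as a minimal-support law (active
offspring concentrated on `{0, c}` with `c` the smallest integer count
making the probabilities feasible; the dormant row must already be
stochastic), so random-environment strategies can be simulated at the
individual level with matching first moments.

The explicit subcritical tail-advantage criterion (`1−d > μ_X` together
with the printed bound on `w`) is checked against the pgf tails: the
crossover generation `n₀` is located numerically, never assumed.

## Fair comparison and phase diagrams

Two strategies are budget-matched when, per environment, (i) active
parents spend the same expected offspring budget with dormant offspring
priced at γ (`m_aᵉ + γ m_dᵉ` equal) and (ii) dormant death
probabilities agree (`dᵉ` equal — the dormant row is compared
unweighted, since waking versus persisting is a state change, not new
spending). At γ = 1 both conditions are plain row-sum equality. The
default tolerance is 1e−9 absolute: all constructions of interest are
exact rationals. Rank classification uses the scale-aware test
`|det M| ≤ 1e−12·(1 + ‖M‖₁²)`.

`classify_point` computes one exponent per strategy (exact for
sleepless/rank-1, Monte-Carlo with a coordinate-derived seed for
rank-2 — defaults 2·10⁴ steps × 8 replicates) and reports the winner,
the count of supercritical strategies, and the advantage class:
*strong* (winner alone supercritical), *advantage-supercritical*
(winner positive but not alone), or *subcritical-all*. Ties within
1e−9 are reported as ties, never broken arbitrarily. Grids clip the
`s1 = s2 = 1` corner to 1 − 1e−9.

The responsive-vs-stochastic separatrix under γ-weighted comparison is
evaluated in closed form; with the budget-matched family at γ = 1/9,
α = 1/20 it is constant in `s1` at `log(40/29)/log(20/9) ≈ 0.4027`, and
plugging any point of the curve back into the two exponent formulas
reproduces equality to 1e−9. A vanishing denominator (pole) returns
NaN rather than raising.

## Problem sizes and reproducibility

Every stochastic routine takes one explicit integer seed and no global
state; batch routines advance replicates in lock-step from a single
generator. Defaults used by the test suite and the acceptance script:
Monte-Carlo oracle 2·10⁴ steps × 8 replicates (standard errors ~3e−3,
ample for 3-σ checks of values of order 0.1); sandwich enumeration to
k = 12; survival fractions at 10⁵ replicates (standard error ~1.4e−3);
growth-dichotomy check at 10³ replicates over 200 generations. The
surviving-run growth-rate check carries a tolerance of 0.05 because the
expected finite-path exponent approaches φ from above (the upper
sandwich at k = 200 is still ≈ 0.02 high) and survival conditioning
selects favorable environment histories; both effects vanish only as
n → ∞.

## Limitations

* Everything is specific to two types and two environment states; the
  general p-type machinery is out of scope.
* Exact exponents exist only in the rank-1 (and commuting/triangular)
  cases; for rank-2 pairs the package brackets φ but does not compute
  it, and no optimization over the spectral scaling λ is attempted.
* The synthetic offspring laws are finite-support with exact means;
  they emulate the branching structure, not overdispersed or
  heavy-tailed reproduction, so simulator-based tests validate the
  mathematics rather than any particular organism's offspring
  distribution.
* The Monte-Carlo estimator's replicates are genuinely independent,
  but within-path correlation means its standard error understates
  nothing only asymptotically; tests therefore use 3-σ bands on top of
  deliberately small tolerances.
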