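# Methods

## Scope and model class

The package solves the chemical master equation (CME) exactly, in the sense
of evaluating the joint probability generating function (PGF) and its
marginals, for *two-level hierarchic first-order* reaction networks:
first-order networks (every reaction consumes at most one molecule) whose
species partition into an independent system I — where splitting and
catalytic reactions may occur, but each reaction produces at most one
independent molecule — and a dependent system II restricted to
monomolecular conversion and degradation, plus zero-order influx reactions.
Autocatalytic reactions (an educt reappearing among its own products with
coefficient above one, e.g. X → 2X) make the characteristic system
nonlinear (Riccati-type) and are rejected with a dedicated error, as are
first-order networks admitting no valid two-level partition (deeper
hierarchies are reported as "not two-level hierarchic" rather than
auto-detected).

Initial conditions are per-species deterministic counts or Poisson means;
mixed products are allowed.  Time-dependent rate constants, bimolecular
networks, SBML I/O and stationary (t → ∞) limits are out of scope.

## Canonical decomposition

Many networks admit several valid partitions (in X → Y + Z either product
may be declared independent).  The canonical choice here is deterministic:
species that never appear as educts are placed in the dependent part —
always feasible, and it is the placement under which the system-II modality
theory applies to them — and among the remaining candidates the partition
maximizing the number of independent species is taken, ties broken by
species order.  All marginal quantities are partition-independent; the rule
only fixes which code path computes them.  `decompose_with` builds a
decomposition from any explicitly chosen valid partition when a
non-canonical one is wanted.

## PGF evaluation: two independent paths

1. **Numeric characteristics** (always valid, including influx b ≠ 0 and
   non-commuting J): the dependent coordinates follow their exact linear
   solution s_dep(τ) = 1 + exp(−Aᵀ(τ−t))(s_dep(t)−1); the independent
   coordinates and the accumulated influx log-factor are integrated
   backward from (s, t) to τ = 0 with an 8th-order Runge–Kutta method
   (rtol 1e−10, atol 1e−12) over complex state, batched over many probe
   points in a single stacked system.  Then g = d(s⁰) · exp(∫ b·(s(τ)−1) dτ).
2. **Closed form** (requires b = 0 and commuting J): s⁰_ind is assembled
   from matrix exponentials of time integrals of J and of exp(−∫J) f, with
   the integrals done by adaptive quadrature of the complex matrix-valued
   integrands (stacked real/imaginary parts) at the same tolerances.

The two paths are coded independently and cross-checked against each other
and against the explicitly known PGFs for catalysis, splitting and decay
chains; this redundancy is the core testing strategy.  Deterministic
initial exponents are capped at 10⁶ to avoid overflow.

A named closed form implements decay chains ("Bateman" networks with
emitted particles) through the standard partial-fraction expansion of the
chain matrix exponential; it requires pairwise-distinct decay rates (the
stable chain end counts as rate zero) and falls back to the numeric path
with a warning otherwise.  Two corrections to commonly mis-printed forms
were validated against the numeric path: the Jacobian definition uses a
Kronecker delta (J_pq = Σ_i Q_pi k_i (δ_pq − c_i R_qi)), and the
inhomogeneity f collects only system-I reactions without independent
products.

## PMF inversion

Univariate marginal PGFs are inverted by evaluating at the M-th roots of
unity and applying the inverse DFT (Cauchy's coefficient formula on the
unit circle — the natural contour for non-negative coefficients of
functions analytic past the closed disc).  M starts at the smallest power
of two ≥ 2(N+1) and doubles until the kept coefficients are stable to
1e−12, which bounds the aliased tail mass.  The largest imaginary residue
is recorded as the pmf's noise floor; truncation defaults to
N = ceil(mean + 10·stddev + 20) (clamped to [32, 2²⁰]), which keeps the
reported mass deficit below 1e−8 for all catalogued models.  Negative
probabilities within max(1e−12, noise floor) are clipped to zero; anything
below −1e−6 is an error (wrong truncation or a non-PGF input), and the
mass deficit is always reported, never hidden.

Cumulants come from Richardson-extrapolated central differences of
κ(ξ) = log g(e^ξ) at step 1e−3; third and fourth cumulants use a wider step
(2e−2) because the h³/h⁴ divisions would otherwise amplify double-precision
roundoff past the truncation error.

## Distribution families and mode detection

`DCP^N` pmfs use the standard compound-Poisson recursion
p_n = (1/n) Σ i·λα_i·p_{n−i}; `KTB^N` pmfs are exact ν-fold convolutions of
the per-trial weight vector in rational arithmetic (probabilities sum to
exactly one), and Neyman Type A is computed as a Poisson mixture truncated
at tail mass 1e−14.  Each has an independent generating-function/FFT route
used as a test oracle.

A count n is a local maximum when p_n ≥ both neighbours with strict
inequality (beyond a tolerance of max(noise floor, 1e−12)·max p) on at
least one side; the boundary uses its single available comparison.  The
weak-inequality definition leaves exact ties ambiguous, so plateaus
collapse to their leftmost point and carry a flag — Binomial(1, 0.5) is
thus reported unimodal with one flagged mode.  For Monte-Carlo pmfs a
moving-average blur (odd window, well below the burst size: window 5 for
the two-stage expression model with burst ≈ 20·mRNA lifetime, window 1 for
the decay chain with burst 2) suppresses sampling noise before counting.

## Modality classification

The verdicts are structural and exact; no numeric pmf is consulted.
Eigenvalue dependence on s_X is decided on the exact characteristic
polynomial det(λI − J(s_X)), computed in sympy with rates rationalized
decimally (degree in s_X is a structural property, robust to that
rationalization).  When the eigenvalues are s_X-independent, the finite
order N is extracted from exp(K) = Σ_k α_k K^k (Cayley–Hamilton), with the
α_k obtained from a confluent Vandermonde solve on the (constant)
eigenvalues and the polynomial matrix powers carried symbolically in
coefficient arrays; the order bound can in principle collapse by accidental
cancellation, so N is evaluated at three random effective times (fixed
seed) and a disagreement raises a diagnostic rather than guessing.  The
commutation of J at two times is tested symbolically (exact) for
n_ind ≤ 6 and n_dep ≤ 3, and numerically at five random time pairs
(tolerance 1e−10) beyond that.

Dependent species with N = 1 that could validly sit in system I
("independent-assignable", e.g. the products of a pure splitting reaction)
are reported unimodal on the independent-species basis; conjectured cases
(finite N > 3) are never silently merged with proven ones.

## Stochastic simulation oracle

The Gillespie direct method provides the independent check: ensembles
sample one end state per trajectory (no time-series reuse), advanced
synchronously in numpy — every loop iteration draws one exponential
waiting time and one reaction choice per active trajectory, exactly as a
per-run direct method would.  Randomness flows from a single seeded
`numpy.random.Generator`, so runs are bit-reproducible given the seed.
Comparisons use total variation ½Σ|p−q|; at 10⁵ trajectories the sampling
contribution to TV stays well below the 0.02 acceptance bound for the
probed models.

## Fixed study conditions

All catalogued models carry literature parameter values; probe times are
not printed in the source figures, so they are fixed here as documented
fixtures: catalysis and conversion+splitting at t = 1.0 s, the
Poisson-initialized two-stage model at t = 1.0 s (the multimodal regime:
extinction spike plus per-mRNA burst clusters; the analytic support stays
modest there), the deterministic two-stage variant at t = 2.7 s, the decay
chain at t = 1.5 s.  Simulation ensembles use 10⁵ trajectories.  The
Binomial-generalized-by-Poisson counterexample stores λ = 10.8 (the value
the burst-size statement fixes; the figure caption's p₂ = 0.8 is recorded
in the provenance string).

## What the built-in models do and do not show

The zoo entries are exact stochastic models, not synthetic approximations
of data — passing tests show that the analytical machinery, the recursions
and the simulator agree with each other and with the printed closed forms
under the stated kinetics.  They do not show that any real biological
system follows first-order kinetics, that extrinsic noise or promoter
switching (absent here) is negligible, or where in parameter space
multimodality actually materializes: a conditionally multimodal verdict is
a statement about the distribution class, and concrete parameters (e.g.
deterministic-IC pure catalysis, whose marginals are Poisson) need not
reach the multimodal subset.  Mapping the multimodal parameter regions is
explicitly out of scope.

## Known limitations

* Only two-level hierarchies; n-level structures are rejected, not solved.
* Influx reactions must produce a single molecule (the vector-b bookkeeping
  assumes it); general zero-order products would need the generic influx
  integrand only.
* The closed-form path's nested quadrature is O(points²) in time nodes and
  is meant for cross-validation at scattered points, not for bulk
  inversion — the numeric path serves that role.
* Very wide marginals (support ≫ 10⁴) make unit-circle inversion expensive
  through the batched ODE solves; no saddlepoint/tail asymptotics are
  provided.
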