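# Methods

## Model and estimator

The ADC profile is modelled as `d(g) = tᵀ a(g)` with `g` a unit 3-vector
and `a(g)` the vector of degree-`n` monomials carrying multinomial
multiplicities; `t` holds the `(n+1)(n+2)/2` distinct entries of a
symmetric order-`n` tensor (units mm²/s).  The package fixes the order-4
listing as `[z⁴, 4yz³, 6y²z², 4y³z, y⁴, 4xz³, 12xyz², 12xy²z, 4xy³,
6x²z², 12x²yz, 6x²y², 4x³z, 4x³y, x⁴]` and the order-2 listing as
`[x², y², z², 2xy, 2xz, 2yz]`; every other module (moment indexing, the
embedded tensor fixtures, file formats) inherits this ordering.

Given signals along `N` directions, tensors are fitted by ordinary least
squares on the normalized log-attenuations `sᵢ = −ln(S(gᵢ)/S0)/b`, i.e.
`t̂ = (GᵀG)⁻¹Gᵀs`.  Noisy magnitudes are clipped below at `1e-12·S0`
before the logarithm: Rician samples can be arbitrarily close to zero and
the estimator must remain finite.  No positivity constraint is imposed on
the fitted profile; the estimator is the plain linear one whose
conditioning the design optimizes.

A second-order tensor `D` embeds exactly into the order-4 model through
`gᵀDg = (gᵀDg)(gᵀg)`; the embedding is used both as a consistency check
(fitting order-4 coefficients to Gaussian-profile signals reproduces the
embedded ADC) and to build isotropic test profiles.

## Condition-number conventions

Two condition numbers are reported everywhere: `κ(G)`, the singular-value
ratio of the design matrix, and `κ(M) = κ(G)²`, the eigenvalue ratio of
the information matrix `M = GᵀG`.  Published summaries of this design
problem sometimes use the two interchangeably; the printed optima satisfy
`1.9141² ≈ 3.6639` and `1.3229² = 7/4`, so the package treats quoted
per-scheme condition numbers as `κ(G)` and the SDP objective `α` as
`κ(M)`, and exposes both fields rather than guessing a single convention.

## The K-optimal design problem

`M` depends on the design only through the degree-`2n` moments
`qⱼ = Σᵢ monomialⱼ(gᵢ)` — 45 values for order 4, grouped by symmetry
class: 3 *pure* (`Σx⁸`-type), 6 *mixed62* (`Σx⁶y²`), 3 *mixed44*
(`Σx⁴y⁴`), 3 *mixed422* (`Σx⁴y²z²`) and 30 odd-exponent moments.  Within
each class moments are stored in descending lexicographic exponent order,
which places `q₁ = Σx⁸` and `q₁₀ = Σx⁴y⁴`.  The basis matrices `Mⱼ` of
the affine map `M(q) = Σ qⱼMⱼ` are derived by exact integer expansion of
`a(g)a(g)ᵀ` — never hand-typed — and the expansion is regression-tested
against the known entry pattern of the `Σx⁴y⁴` matrix (weights 1, 16, 36
coupling the `y⁴/x⁴`, `4xy³/4x³y` and `6x²y²` slots).  The per-point
unit-norm constraints are convexified into the single linear identity
`uᵀq = N`, where `u` holds the multinomial weights of
`(x²+y²+z²)ⁿ` (for order 4: fifteen nonzero entries with values
1, 4, 6, 12 in class sizes 3/6/3/3).

Two formulations of `min κ(M(q))` s.t. `M(q) ⪰ 0, uᵀq = N` are kept:

* **line_search** (reference): for fixed `c ≥ 0` the LMI
  `min α : I ⪯ cM(q) ⪯ αI, uᵀq = N` is solved and its optimum `α_c`
  minimized over `c` — a geometric sweep of 25 points over
  `c ∈ [1e-2, 1e3]·(m/N)` clipped to the feasible region
  `c ≥ 1/max_q λ_min(M(q))` (the boundary point is always included: for
  order 2 the minimizing `c` sits exactly on it), then golden-section on
  `log c` until the bracket's `α` spread is below `1e-5`.  Feasibility of
  a given `c` is decided against `max λ_min` computed once per `(order,
  N)`; `c = 0` is reported infeasible, not raised.  A sub-`1e-3` slack in
  `I ⪯ cM` left by the smoothed subproblem solver is absorbed by
  rescaling `c`, keeping every reported `α_c` an exact LMI value.
* **direct**: scale invariance of `κ` collapses the problem to the single
  program `min λ_max(M(q))` s.t. `λ_min(M(q)) ≥ 1`, rescaled afterwards
  so `uᵀq = N`.  This is the default (one solve instead of ~30) and the
  two methods agree to better than `1e-3` relative.

### Eigenvalue smoothing solver

No semidefinite-programming library is part of the package's dependency
set; the LMI subproblems are instead solved by a purpose-built smoothed
extremal-eigenvalue optimizer.  Extremal eigenvalues are nonsmooth exactly
at K-optimal solutions (the optimum clusters both eigenvalue ends), so
the solver works with the exponential surrogates
`smax_μ = μ log Σ exp(λₐ/μ) ≥ λ_max` and
`smin_μ = −μ log Σ exp(−λₐ/μ) ≤ λ_min`, whose gradients are
softmax-weighted spectral projectors.  Because the surrogates bound the
true eigenvalues one-sidedly, every iterate certifies a feasible
condition number, and the per-stage smoothing gap is at most `μ log m`.
The temperature is driven from `1e-1` to `1e-6` (relative to the matrix
scale) by continuation, each stage solved with SLSQP; across stages the
iterate with the best *exact* condition number is kept.  The start is the
moment vector of the uniform sphere measure
(`E[x^{2a}y^{2b}z^{2c}] = (2a−1)!!(2b−1)!!(2c−1)!!/(2n+1)!!`), strictly
feasible and symmetric.  The solver is deterministic; results are cached
per `(order, N, method)`.

Achieved accuracy (order 4): `α* = 3.66333`, class constants
`N/q* = 4.5259 / 101.833 / 248.100 / 1244.65`, within 0.1% of the
published 4.5248 / 101.8849 / 248.2622 / 1245.3300 and stable to ~2e-6
across random feasible starts — the relaxed optimum appears unique.  For
order 2 the solver reproduces `α* = 1.75` (`κ(G)* = √7/2`) to 1e-5.

## Point extraction

Matching `q*` gives 45 polynomial equations; the `N` unit-norm equations
are eliminated by normalizing each point inside the residual, so the
unknowns are unconstrained 3-vectors and the solver is trust-region
nonlinear least squares (analytic Jacobian through the normalization).
Residuals are scaled `1/N` so the default tolerance (`1e-6`, infinity
norm) is size-independent.  Restarts (default 20) alternate uniform
sphere points with jittered Fibonacci spirals; the seed controls both,
the first restart below tolerance is returned, and per-restart residuals
are logged.  Extracted points are exactly normalized, so the certified
design is feasible for the original problem — this is what upgrades the
relaxation bound to global optimality.

**Minimal designs.**  For order 4 the extraction system is *not* solvable
at the minimal size `N = 15`: 15 unit vectors carry 30 spherical degrees
of freedom against 44 independent moment equations (`uᵀq = N` holds
automatically), an overdetermination of 14.  Extensive multistarts
plateau at a scaled residual of ~1.6e-3, and all octahedrally symmetric
15-point families (the only way such an overdetermined match could close)
miss by two orders of magnitude more.  Equivalently, no antipodally
symmetric 30-point optimal design exists, since degree-8 moments are even
under `g → −g`.  `extract_points` therefore raises a convergence error at
`N = 15` that reports the best residual reached.  At `N = 30` (and for
order 2 at `N = 6`) extraction reaches residuals of order 1e-14 and
`κ(G) = 1.913982`, matching the SDP bound to six digits.  Near-solutions
are useless here: the odd-moment basis matrices carry integer weights up
to 144, so a residual of 1e-3 already inflates `κ` severalfold.

## Rotational-variance evaluation

* **Rotation grid**: `R = Rx(θ)Ry(φ)Rz(ψ)` on a product grid of `steps`
  equispaced values per angle over `[0, π)` including 0 (343 rotations at
  the default `steps = 7`, identity included).  Even-order profiles are
  antipodally symmetric, so half-turns suffice; the reported mean/sd over
  rotations are insensitive to the convention at the two significant
  digits quoted, and the grid is configurable.
* **Tensor rotation**: the covariant transform of the full symmetric
  tensor, `T'_{ijkl} = R_{ia}R_{jb}R_{kc}R_{ld}T_{abcd}`, expanding the
  15 coefficients to 81 entries and recompressing.  The testable contract
  is `ADC_{t'}(g) = ADC_t(Rᵀg)`.
* **Noise model**: magnitude MR noise, `measured = √((S+ε₁)² + ε₂²)` with
  independent `ε₁, ε₂ ~ N(0, σ²)`, `σ = S0/SNR`.  The Rayleigh limit
  (mean `σ√(π/2)` at `S = 0`) is verified by simulation.
* **Signal deviation**: `η = (1/N)Σ|S(gᵢ) − Ŝ(gᵢ)|/S0` with `S` the
  *noisy* measured signal and `Ŝ` the signal of the refitted tensor.  The
  absolute value is essential — a signed mean would vanish by
  construction — and `η` is `S0`-invariant, so all simulations use
  `S0 = 1`.
* **Experiment**: per rotation, `n_mc = 200` trials of simulate → fit →
  deviate, using one pseudoinverse of `G` precomputed for all rotations
  and trials; defaults `b = 1500 s/mm²`, `SNR = 12.5`.  A single
  generator seeded by the configuration drives all draws, making results
  bit-reproducible.  With the published 30-direction scheme and the
  single-fiber tensor `t01` this yields mean `η̄ ≈ 0.049` and
  `sd(η̄) ≈ 0.0009–0.0010` across seeds (sample sd, ddof = 1).

The ten embedded evaluation tensors (`t01`–`t10`, values ×1e-4 mm²/s)
cover single fibers, two-fiber crossings at 60–90° with lobe weights
1:1–4:1, and three perpendicular fibers; with `b = 1500 s/mm²` the
resulting `b·d` ranges up to ≈3.6, spanning realistic attenuation levels.

## What the simulations do and do not show

The Monte-Carlo study emulates orientation dependence of a noisy
acquisition under an exact model class: the ground truth lies inside the
order-4 tensor family, noise is independent Rician per direction, and
`b`, `S0` are spatially constant.  Real acquisitions add model mismatch,
spatially varying and correlated noise, motion and eddy-current effects;
passing tests therefore validate the design machinery and the estimator's
conditioning claims, not end-to-end in-vivo performance.

## Numerical choices and limitations

* Solver tolerances: smoothing continuation to `1e-6` relative, SLSQP
  `ftol = 1e-14`, iteration cap 150 per stage; comparisons against
  published optima use 2e-3 relative.
* Strict LMI inequalities are implemented as closed ones; optima lie on
  the boundary as usual in semidefinite programming.
* Problem sizes in tests: SDP solves at `N ∈ {6, 12, 15, 30, 60}`,
  extraction at `N ∈ {6, 30, 30+30}`, the full 343×200 Monte-Carlo for
  all ten tensors (~7e5 simulated fits); the whole suite runs in a few
  minutes on one CPU.
* Orders beyond 4 are not exercised: the basis generator is
  order-generic, but solver and tests are validated only for `n ∈ {2, 4}`.
* The non-uniqueness of K-optimal designs is demonstrated (different
  seeds give moment-equivalent point sets; unions of optimal designs are
  optimal) but not classified or enumerated.
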