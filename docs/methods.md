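# Methods

## Scope and model

`entroage` quantifies tissue aging through entropy on two coupled
timescales: a fast metabolic one, τ, on which a kinetic (BGK-type)
relaxation model describes the nonequilibrium steady state of a living
tissue, and a slow degradation one, T = Nτ with N ~ 3×10⁷ for mammals, on
which structure is lost and entropy-based age statistics grow. All model
quantities are dimensionless; only the allometry module carries physical
units (seconds).

## Entropy functionals

Statistical entropy uses the convention 0·log 0 = 0 (implemented through
`scipy.special.xlogy`). The KL divergence `D(p‖q) = Σ p log_b(p/q)` is
offered in two modes because the underlying formula is written over
*densities*, not probabilities:

- **normalized** (default for trajectory statistics): both vectors are
  rescaled to unit mass, which guarantees `D ≥ 0` with equality iff
  `p = q` (Gibbs inequality, property-tested);
- **raw**: the literal sum over unnormalized densities, which may be
  negative. This mode exists because the order-of-magnitude anchor — a
  density ratio of 10⁹ contributing log₁₀ = 9 — is a statement about raw
  densities.

The KL log base defaults to 10 to reproduce that anchor; entropy defaults
to the natural log. Densities are clamped at a configurable floor (default
1e-12) before ratio evaluation, with a logged warning; passing `floor=0`
disables clamping, in which case a vanishing `q` under positive `p` raises
a support error naming the compartment.

Combinatorial entropy is the multinomial multiplicity `ln(N!/Π nᵢ!)`
evaluated through log-gamma, so large totals never overflow. It is zero
when one cell holds everything and maximal at equal occupation; we take
this standard Boltzmann counting as the definition of the configurational
disorder of occupation numbers.

## Kinetic model

The stationary equation `ξ ∂f/∂x = (f_M[f] − f)/τ` is closed
self-consistently: `f_M` is the Gaussian in ξ sharing each node's
quadrature moments (ρ, u, θ) of `f` itself (standard nonlinear BGK).
Discretization:

- **Grids.** 64 uniform x-nodes on [0, 1] and 32 Gauss–Legendre ξ-nodes on
  [−8, 8] by default, both configurable. Even node counts keep ξ = 0 —
  where the transport characteristic degenerates — off the grid. The
  quadrature weights define the velocity interval; Gauss nodes never reach
  its endpoints.
- **Boundary conditions.** Inflow Maxwellians at both walls: the basal
  wall (x = 0) injects for ξ > 0, the surface wall (x = L) for ξ < 0. This
  is the minimal standard closure for a two-wall stationary problem.
- **Solver.** Implicit first-order upwind sweeps (exact per-column solves
  given `f_M`) alternated with moment/Maxwellian updates, under-relaxed by
  0.9; convergence when the max-norm change between iterates falls below
  `tol` (default 1e-8, `max_iter` 1e4). Non-convergence raises an error
  carrying the residual history. Exact limits are tested: identical
  equilibrium walls reproduce the global Maxwellian, and τ → ∞ recovers
  free streaming.
- **Quadrature accuracy.** Gauss–Legendre moments of a Gaussian are
  spectrally accurate but degrade for very narrow (θ ≲ 0.5) or poorly
  contained (|u| + 4√θ ≳ ξ_max) states: at 32 nodes on ±8 the θ-error is
  ~1e-10 for θ ≈ 1 but ~1e-5 for θ = 0.5. Properties asserted at the 1e-9
  level (moment conservation, H-theorem margins) are therefore tested on a
  64-node grid spanning ±10 with moment parameters θ ∈ [0.5, 1.2],
  |u| ≤ 1, where the target-Maxwellian moment error is ~1e-13.

Local entropy is the moment `S(x) = −Σ_j w_j f log f` (natural log,
0·log 0 = 0). The equilibrium profile is the same functional applied to
the moment-matched Maxwellian; it bounds the nonequilibrium profile from
above at every node because the Maxwellian maximizes −∫ f log f among
distributions with fixed (ρ, u, θ).

The spatially uniform relaxation `∂f/∂t = (f_M − f)/T` freezes its target
at the initial moments — BGK relaxation conserves the hydrodynamic
moments, so the target never moves — making the trajectory exactly
`f(t) = f_M + (f₀ − f_M)e^{−t/T}` (cross-checked against an independent
ODE integration). Every state on it is a convex combination of `f₀` and
`f_M`; entropy is non-decreasing along it (H-theorem) and the structural
analogue with timescale T reuses the same operators: the stationary
structural equation is served by the stationary solver with τ → T, and
`StructuralState` carries its energy coordinate as a passive binning axis
(no dynamics over energy are modelled).

The age statistic `ΔS = ∫₀^L_old (S_old − S_young) dx` interpolates both
profiles linearly onto their merged node set restricted to [0, L_old] and
applies the trapezoid rule — the simplest quadrature consistent with
piecewise-linear data; it is antisymmetric under swapping the profiles and
is validated against a 1e5-point Riemann sum.

## Stochastic aging simulator

What the generator emulates: a surface density field over 40 independent
compartments, roughened by fast metabolic noise and depleted by slow
thinning, whose KL divergence from the young baseline grows with
iteration count. Choices where the conceptual description leaves freedom:

- **Noise law**: multiplicative uniform factors `1 + U(−a, +a)`,
  independent per compartment and iteration, amplitude default a = 0.1 —
  positivity-preserving, scale-free, and mean-preserving (verified by a
  Monte-Carlo oracle). Amplitudes ≥ 1 are rejected.
- **Thinning law**: an absolute decrement (default 0.002) every
  `slow_every` fast steps (default 1) — the simplest strictly monotone
  depletion. The literal biological scale separation (N ~ 3×10⁷ fast steps
  per slow step) is emulated at desk scale by a small per-step rate; the
  ratio is configurable.
- **Floor**: densities are clamped at 1e-9, nine decades below the unit
  baseline — the order at which a compartment counts as fully degraded,
  matching the nine-decade KL anchor.
- **Defaults**: 500 iterations, snapshots every 10 (memory/fidelity
  balance), KL in normalized mode, base 10, baseline = iteration-0
  profile. The young profile is constant 1.0 (an optional gentle cosine
  modulation of relative amplitude ≤ 0.05 is available).

What it does **not** emulate: keratinocyte lineage or differentiation,
spatial coupling between compartments, wrinkle geometry, or any
calibration to histology. Passing tests therefore demonstrate the
qualitative entropy-growth mechanism — not quantitative claims about real
epidermis.

The schematic entropy-profile generator is likewise illustrative: young
and old curves rise quadratically from their basal baselines to the common
dead-cell maximum at their own surface, with seeded uniform fluctuations
that grow with age; the old tissue is thinner, starts more entropic, and
is clipped to dominate the young curve on their common support so the age
integral is positive by construction.

## Allometry

`N = (T/t_H) / (τ/t_H)` with the mammalian anchors T/t_H ~ 1e9 and
τ/t_H ~ 30; ratios are computed exactly and rounded only for display. The
human deviation (2–3× more beats per lifetime) is an optional
multiplicative correction, default 1, rather than a hard-coded species
table. Whether the metabolic τ here and the kinetic relaxation τ are the
same physical quantity is left open; the package treats them as one
symbol.

## Problem sizes and reproducibility

The test suite and the acceptance script use a 20-seed ensemble of
500-iteration simulations, the default 64×32 kinetic grid, and 100 random
initial states for the relaxation properties — sizes chosen so the whole
verification runs in well under a minute while leaving the ensemble trend
statistically unambiguous. All randomness flows through
`numpy.random.default_rng` seeded once per run; CLI runs write a JSON
configuration echo (including the resolved seed) sufficient to reproduce
them exactly.

## Known limitations

- 1-D transport with a relaxation collision operator only; no full
  Boltzmann kernel, no time-dependent inhomogeneous solver, no 2-D/3-D.
- First-order upwind discretization: O(Δx) accuracy, validated by grid
  refinement rather than exact solutions in the collisional regime.
- The equilibrium-dominance and moment-conservation inequalities hold up
  to velocity-quadrature error; poorly resolved states (θ far from 1 on
  the default grid) can show apparent violations at the quadrature-error
  level.
- The KL trajectory's reference level of 1 (the `|D − 1|` statistic) is a
  conventional choice for the trend plot, not a derived threshold.
- No estimation from images or clinical data; all inputs are synthetic or
  user-supplied profiles.
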