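# Methods

## Models

All three models are continuous-time Markov jump processes on integer
population vectors **N** = (N₁, N₂, N₃) obeying stochastic mass-action
kinetics, chosen so that the expected jump rates reproduce the cyclically
symmetric May–Leonard mean field.  Species indices are cyclic mod 3
(0-based internally, 1-based in output).

**General-variance (GV).**  Five reaction templates per species: birth
`A_i → 2A_i` (rate constant b), death `A_i → ∅` (d), homocidal competition
`2A_i → A_i` (2/Ω), and heterocidal competition `A_i + A_{i+1} → A_{i+1}`
(α/Ω) and `A_i + A_{i+2} → A_{i+2}` (β/Ω).  Mean field:
`dN_i/dt = N_i[(b−d) − (N_i + αN_{i+1} + βN_{i+2})/Ω]`.  The b/d split does
not affect the mean field; only r = b − d does.  Where a concrete split is
needed (simulation defaults) we use b = 2, d = 1 — the smallest integer
split with strictly positive death rate, which is what distinguishes the GV
model's asymptotics — and both are configurable.

**Minimal.**  The GV network with the death channel deleted and b = r.
For fixed r this is the minimum-variance mass-action implementation of the
same mean field.  The deletion changes the state-space connectivity: the
only remaining death mechanism (homocide) needs two individuals, so a
species with one survivor can never reach zero and the origin is
structurally unreachable from any nonzero state.

**Three-pool.**  Active-cell counts N_i in pools of fixed size Ω with
implicit inactive counts M_i = Ω − N_i: self-activation `A_i + I_i → 2A_i`
(1/(τΩ)), inhibition of pool i by pool i+1 `A_i + A_{i+1} → I_i + A_{i+1}`
(γ/(τΩ)), endogenous activation `I_i → A_i` (μ/τ).  Every reaction
conserves N_i + M_i, so the lattice [0, Ω]³ is invariant; with μ > 0 no
stall is permanent.

**Propensity convention.**  Combinatorial mass action: first order c·N,
mixed second order c·N_A·N_B, self second order c·N(N−1)/2.  With the
homocidal constant c = 2/Ω the net homocide rate is N(N−1)/Ω, which is the
unique convention under which the summed stoichiometry-weighted propensities
equal the mean-field drift plus exactly the combinatorial correction N_i/Ω
(GV/minimal) or the drift exactly (three-pool).  Both identities are
enforced by property tests at random states.

## Parameters

| symbol | meaning | units | typical / default |
|---|---|---|---|
| b, d | per-capita birth / death (GV) | 1/time | 2, 1 (r = 1) |
| r | net growth rate (minimal) | 1/time | 1 |
| α, β | heterocidal strengths (i+1, i+2 on i) | — | 0.8, 1.3 (heteroclinic regime) |
| Ω | system size: carrying capacity (GV/minimal, positive real) or cells per pool (three-pool, positive integer) | — | 3–30 |
| τ | three-pool time constant | time | 1 |
| γ | inhibition strength | — | 2.4 |
| μ | endogenous activation | — | 10⁻⁵–10⁻¹ |

Ω may be a non-integer for GV/minimal (it only scales rate constants;
states remain integers); it must be a positive integer for the three-pool
model, where it bounds the state space.

## Simulation

Gillespie's direct method, exact: exponential waiting time at the total
propensity, reaction chosen proportionally.  Hot loops are numba-jitted;
each replicate k of an ensemble reseeds its own stream with
(base_seed + k) mod 2³¹, so results are order-independent and reproducible
byte-for-byte from (network, initial state, t_max, seed).  No tau-leaping or
diffusion approximation is offered: exactness at desk scale is the point.

## Poincaré sections and cycle lengths

Section P_i is the plane N_{i+1} = N_{i+2} restricted to the triangle with
vertices (0,0,0), (Ω,Ω,Ω), Ω·e_i.  The valid crossing direction is fixed
once per model: the sign of the mean-field flux through P₁ at the
representative interior point (Ω/2)(1,1,1) + (Ω/4)e₁.  The same sign fixes
the cyclic order in which a circuit visits the sections — P₁→P₂→P₃ for the
three-pool model; for the minimal model with β > α the flux is reversed and
the natural circuit is P₁→P₃→P₂.  Making the circuit order follow the
computed orientation (rather than hard-coding P₁→P₂→P₃) is a design choice;
it keeps "one cycle = one revolution around the diagonal" true for every
model.

On the integer lattice a jump crosses P_i when the oriented coordinate
D = ±(N_{i+1} − N_{i+2}) passes from negative to nonnegative (a landing
exactly on the plane is attributed to the side being left, i.e. ties break
toward "crossing completed"), subject to N_i ≥ max(N_{i+1}, N_{i+2}) so the
mirror half of the plane through the diagonal does not count.  How to detect
discrete crossings is genuinely underdetermined (tie handling on the
lattice); this rule is flagged as a package choice, and the jitted online
detector and the pure-Python post-hoc detector are tested to agree event for
event.  Continuous trajectories use interpolated sign changes refined by
root bracketing, with the triangle test N_i ≥ (N_{i+1} + N_{i+2})/2 at the
crossing point.  A cycle length is the time between successive
anchor-section crossings after the other two sections were crossed in
circuit order; intervening re-crossings (noise wiggles) are ignored.

## First-passage analysis

The chain is truncated to {0..n_max}³ (default n_max = 2Ω).  Transitions
that would leave the lattice are deleted — the probability-conserving
realization of an adjoint-reflecting boundary — and the coordinate planes
N_i = 0 (or only the origin) are made absorbing by zeroing their outgoing
rates.  Row sums of the assembled generator are checked to ≤ 10⁻¹² on every
build.

All solves use a single sparse LU factorization of the transient block
Q_TT (SuperLU), with residuals checked against 10⁻¹⁰:

* hitting probabilities per absorbing class: Q_TT h = −R·1_s;
* mean absorption times: Q_TT τ = −1;
* absorption *distribution* from one initial state: the adjoint solve
  Q_TTᵀ ρ = −e_{x0} followed by flux Rᵀρ — one solve instead of one per
  absorbing state.  The backward and adjoint routes are asserted to agree on
  small chains.

The conditional second-extinction problem restricts to the two-species
subsystem on N₃ = 0 (species 1 killed by 2 at strength α, 2 by 1 at β),
absorbs on both remaining axes, and averages the absorption distribution
over the entry distribution — the exact 3-D hitting distribution on the
plane N₃ = 0, renormalized — again via one adjoint solve.

Stationary distributions of non-absorbing truncated chains are computed on
the closed communicating class reachable from a supplied initial state
(strongly connected components of the rate graph); if several closed classes
are reachable the problem is reported as ambiguous rather than silently
resolved.  The class-restricted null space is solved with one row of the
adjoint replaced by the normalization.

Extensional notes: the interior equilibrium of the minimal mean field is
Ωr/(1+α+β)·(1,1,1) (≈ Ω/3.1 for α = 0.8, β = 1.3); the rounded reference
point Ω/3·(1,1,1) is used only as an initial condition.  Field slices
default to the plane N₁+N₂+N₃ = Ω, the plane containing that reference
point; any total is selectable.

## Statistics

The zero-truncated Poisson pmf is evaluated in log space with the
normalization log(e^λ − 1) = λ + log1p(−e^{−λ}).  The empirical stationary
law of the minimal model is estimated from the sole survivor after the
second extinction: a burn-in of 10 mean reaction times (10/total propensity
at the extinction state), then the count sampled at regular intervals —
regular-interval sampling is time-weighting, as required for a
continuous-time stationary law, and the interval is several relaxation times
(1/r) so samples are approximately independent for the χ² test.  χ² binning
merges adjacent support points left to right until each expected count
reaches 5 (the classical rule; the binning itself is reported).  Gamma fits
are two-parameter MLE with the location pinned at zero
(`scipy.stats.gamma.fit(floc=0)`).  CV standard errors use the
normal-approximation delta method CV·√(1/(2(n−1)) + CV²/n); a moment-based
(fourth-moment) estimator backs the variance SE.

## Problem sizes used by the test suite

Exact solves use Ω = 8–12 (lattice ≤ 25³ ≈ 1.6·10⁴ states; Ω = 30 ≈
2.3·10⁵ states is supported but slow), SSA ensembles use 10⁴ replicates per
initial state for extinction-time comparisons, 2000 cycles per parameter
set for cycle statistics, and 3000 strided samples for stationary-law
goodness of fit.  These sizes give Monte-Carlo errors comfortably below the
assertion tolerances (e.g. relative SE ≈ 1% for 10⁴-sample extinction-time
means) while keeping the whole suite interactive.

## What the generated data do and do not show

All inputs are generated internally: the models themselves are the data
source.  Passing tests therefore validate the mathematics — exactness of
the simulator against closed forms (Yule growth, gambler's ruin, pure-death
harmonic sums, truncated-Poisson null spaces), consistency between
independent exact and Monte-Carlo routes, and the qualitative regime
structure — not the fidelity of any of the three models to a particular
ecosystem or neural circuit.  Real populations have non-mass-action
interactions, environmental (not just demographic) noise, spatial structure
and sensory feedback, all outside scope.

## Known limitations

* Exact first-passage analysis scales as O(n_max³) states; beyond Ω ≈ 30
  (≈ 2·10⁵ states) factorization time and memory grow quickly, and SSA is
  the intended tool.
* The m = 3, cyclically symmetric case only; no asymmetric per-species
  rates.
* Heteroclinic mean-field trajectories approach coordinate planes
  exponentially; below ~10⁻¹² the integrated components are at the noise
  floor of the tolerances (rtol 1e−8/atol 1e−10 defaults; the regime tests
  use 1e−10/1e−12), which bounds how many successive circuit durations are
  meaningful.
* The Gamma(3, τ/(μΩ)) cycle-length law is an asymptotic statement for
  small Ω and μ; it degrades as Ω grows and more escape paths contribute,
  where the mean approaches the deterministic period instead.
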