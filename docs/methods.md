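# Methods

## Modelling framework

The state of the system is a collection of `N` agents with phase-space
variables `z_i = (x_i, v_i)`.  The structural variable `x_i` encodes the
agent's place in an interaction network — a point of the periodic unit
interval `[0, 1)` in the continuum setting, a node index in the discrete
setting — and is frozen for all time.  Interactions are binary and
directed: the ordered pair `(i, j)` (i active, j passive) fires at rate
`w(x_i, x_j)/N`, and on firing draws increments `(a, b)` from an
interaction measure `nu_{z_i, z_j}`; in all three shipped models the
active agent is unchanged (`a = 0`).  The `1/N` factor is the mean-field
scaling: the total rate at which one agent is affected stays `O(1)` as
`N` grows, so an `N -> infinity` limit exists.

Because positions never move, the spatial marginal `eta` of the one-agent
distribution is **exactly** stationary — not approximately, and not only
in the limit.  This is the sharpest invariant the package tests: the
empirical position histogram of a simulation run is bit-identical across
snapshots.

### Levels of description

* **Gillespie simulation** (`interaction_core.simulate_boltzmann`).  An
  exact event-driven realisation: exponential waiting times with the
  total event rate, pair selection proportional to `w(x_i, x_j)`,
  increments sampled from the rule.  Exactness (rather than tau-leaping)
  was chosen deliberately so that conservation tests are sharp; at the
  problem sizes used here (N up to a few thousand, 10^3–10^4 events) the
  event loop is not a bottleneck.  Unary channels — single-agent
  transitions at state-dependent rates, used for SIR removal — are an
  explicit extension of the pure pair framework.

* **Vlasov particle method** (`meanfield.solve_vlasov_particles`).  When
  increments are small, the jump process is approximated by deterministic
  drift along characteristics.  Since characteristics do not move in `x`,
  a weighted particle set `(x_p, V_p, m_p)` evolves by the closed ODE
  system `dV_p/dt = sum_q m_q w(x_p, x_q) D(V_p, V_q)`, where `D` is the
  state part of the drift assembled from the rule's mean increments.  The
  empirical measure of the particles is an exact weak solution of the
  Vlasov equation, so the only numerical error is time discretisation
  (fixed-step RK4 by default, explicit Euler optional).

* **Monokinetic closure** (`meanfield.solve_monokinetic` and the
  model-specific field equations).  Measures of the form
  `eta(dx) ⊗ delta_{V(x,t)}(dv)` stay of that form; the field `V` solves
  a nonlocal equation integrated by the method of lines on the kernel's
  quadrature discretisation.

Time units: the mean-field regime rescales time by the rule's small
parameter (`gamma/(1+gamma)` for the dialect rule, `h = 1/J` for the
social rule).  Mean-field coefficients are rescaled by default; the agent
simulator always runs in raw (unrescaled) time and comparisons divide by
the rescale factor.  The diffusion coefficient `A` of the second-order
(Fokker–Planck) approximation is assembled and tested for symmetry and
positive semidefiniteness, but the Fokker–Planck PDE itself is not
solved; only first-order (Vlasov) and monokinetic dynamics are integrated.

## Kernels and discretisation

Kernels on `[0, 1)` use the periodic distance
`d(x, y) = min(|x−y|, 1−|x−y|)` by default (the reference epidemic
scenario has kernel support 0.2 < 1/2, which makes the periodic
convention unambiguous; a truncated non-periodic variant is available via
a flag).  Quadrature is the rectangle rule with weight `h` on the uniform
node-centred grid `x_i = i·h` — matching the explicit-Euler finite
difference setting of the reference numerics; the discretised kernel
matrix stores `w(x_i, x_j)·h` so that matrix–vector products are
integrals.  The diagonal is **included** for continuum-derived grids (the
defining integrals include `x~ = x`) and **excluded** for agent pair sums
(which run over `i != j`); both are explicit flags.

The nonlocal Laplacian `Δ_w f = ∫ w(x, y)(f(y) − f(x)) dy` annihilates
constants exactly and, for symmetric kernels, conserves the quadrature
integral to rounding — both are tested rather than assumed.

Narrow kernels `w = ε⁻¹ k(d/ε)` with an even profile `k` of unit mass and
second moment `C` satisfy `∫ w (f(y) − f(x)) dy = (Cε²/2) f'' + O(ε⁴)`,
giving the local diffusion scale `σ = sqrt(C)·ε`.  The box profile
(`k = 1/2` on `[−1, 1]`, `C = 1/3`) is the default; the triangular hat
profile (`C = 1/6`) is preferred in convergence studies because its
continuity keeps the rectangle-rule quadrature second order through the
kernel edge.

## Dialect model

States are memory vectors on the simplex `K = {v >= 0, sum v = 1}` over
`M` variants.  A speaker picks variant `i` with the conformity-biased
probability `p_i(v) = v_i^alpha / sum_j v_j^alpha` (`alpha >= 1`; corners
map to themselves under the convention `0^alpha = 0`, the continuous
extension from the interior).  The listener blends the heard variant:
`v' = v/(1+gamma) + gamma/(1+gamma) e_i`.  Defaults `M = 2`,
`alpha = 2`, `gamma = 0.1` — a weak single-interaction impact, which is
the regime where the Vlasov approximation is meaningful.

The monokinetic field equation has reaction part `−κ(x)(V − p(V))` with
`κ(x) = ∫ w(x, y) ρ(y) dy` and a nonlocal diffusion acting on `p(V)`.
The reaction is multistable with stable states at the corners of `K`
(phase separation); the symmetric state is unstable with linear growth
rate `κ(α−1)` for `M = 2` (the choice map has slope `α` at the symmetric
point), which the tests verify to 5% from a small-perturbation run.
The quadratic variation `V(t) = ∫∫ |v − V̄(x,t)|² f dz` of the Vlasov
dynamics decays at rate `>= 2 κ₀` with equality for spatially constant
`κ`; with a constant kernel of unit mass (`κ ≡ 1`) the particle solver
reproduces the rate 2 to better than one part in 10⁹, so the test
tolerance of 2% is dominated by nothing but the fit window.

Local limits: `burridge` (diffusion on `p(V)`), `allen_cahn_V` (diffusion
on `V`; the leading-order simplification when `κ ≫ σ²`) and
`allen_cahn_P` (the same dynamics advanced in the probability variable
`P = p(V)`, converted back through the closed-form inverse
`v_i = P_i^{1/α}/Σ_j P_j^{1/α}`).  Default step `dt = 0.2 h²/σ²`; steps
beyond the diffusive stability scale trigger a warning.  The
per-position mean equation at the Boltzmann level is not closed (the
choice map is nonlinear), so it is exposed only as a diagnostic
comparison between simulator means and the monokinetic field, never as a
solvable equation.

## Social-construction model

Raw states are integer weights `omega` over `M` representations plus an
interaction count `I`; rescaling by a large constant `J` (`v = omega /
sum omega`, `s = I/J`, increment `h = 1/J`) puts the model in the
framework with state `(v, s)`.  The active agent plays the representation
of **highest** weight, ties uniform.  Ties are detected by exact equality
after rounding to 12 decimals — on the rational grid the raw model
inhabits, true ties are exact, and the rounding only guards float noise.
The update `v' = s/(s+h) v + h/(s+h) e_i`, `s' = s + h` is algebraically
identical to incrementing `omega` and rescaling, an identity the tests
check exactly.

The monokinetic system `dV_k/dt = Σ_l w_kl (s_k⁰ + λ_k t)⁻¹ (p(V_l) −
V_k)` with `λ_k = Σ_l w_kl ρ_l` uses the closed form `s_k(t) = s_k⁰ +
λ_k t` for the interaction count.  The argmax map is discontinuous, so
solutions may be non-unique at ties; the solver therefore offers both the
literal `argmax` map (fixed small-step integration, used for qualitative
phase-separation tests) and a `smooth` regularisation substituting the
conformity map with a large exponent (used where quantitative accuracy
matters).  Note that the argmax rule is the *sharp-selection* limit of
the conformity family — formally the large-exponent limit of
`v^α/Σ v^α` — and the implementation follows the verbal argmax
description.

## Epidemic model

Compartments S/I/R with densities `u, v, r`.  The only pair interaction
is infection of a passive susceptible by an active infected, giving the
nonlocal system `∂_t u = −u·K[v]`, `∂_t v = u·K[v] − βv`, `∂_t r = βv`
with `K[v](x) = ∫ w(x, y) v(y) dy`.  Two algebraically identical forms
are implemented (direct, and `α u v + u Δ_w v` with `α(x) = ∫ w dx~`) and
tested against each other; note the mass-action coefficient `α(x)` and
the kernel amplitude are distinct objects held in separate fields.  The
explicit Euler scheme with `dt = 0.01` (the reference scenario's step)
conserves `u + v + r` pointwise **exactly** — the three increments sum to
zero before rounding — and preserves `u`-monotonicity since
`u_{n+1} = u_n (1 − dt·K[v_n])` with `dt·K[v]` well below one at the
scenario's scale.

The reference scenario: periodic unit interval, 100 grid points,
triangular kernel `0.3·(0.2 − d)₊`, `β = 0.1`, `u₀ ≡ 1`, infected peak at
`x = 0.5`, horizon `t = 5`.  The peak shape is specified only as "narrow"
in the underlying model description, so the package fixes the default
`v₀(x) = 0.05·exp(−(x−0.5)²/(2·0.02²))`; every invariant test is
shape-independent.  The comparison reaction–diffusion model's
diffusivities are likewise not canonical; the default `D₁ = D₂ = 1`
(with the kernel's own scale carried by `Δ_w`) is flagged in the
configuration, and the qualitative network-vs-comparison contrasts are
recorded as configuration-dependent.

The local limit `∂_t u = −αuv − u Δv` is shipped **as a demonstrator of
ill-behaviour**: the cross-diffusion operator is not normally elliptic,
and wherever the infected profile is concave enough (`Δv < −αv`) the
susceptible density increases, violating the model's basic monotonicity.
The solver records every grid point where this happens; a blow-up guard
aborts with a diagnostic.  Production use should rely on the nonlocal
system or the leading-order (diffusion-free) local SIR equations.

## Synthetic data

All test inputs are generated in code (`io_cli.generate_fixture`):
uniform random agent positions with Dirichlet simplex states, block
two-community networks (strong intra-, weak inter-community weights),
Gaussian peaked fields, and interior simplex fields.  These emulate the
study conditions of the framework — spread initial memories, community
structure, a localised outbreak — but deliberately not the features of
real data (empirical mobility matrices, heavy-tailed degree
distributions, measurement noise); passing tests therefore demonstrate
the internal consistency of the multilevel hierarchy, not calibration to
any observed system.

## Numerical choices and problem sizes

* Integrators: fixed-step RK4 by default, explicit Euler to mirror the
  reference numerics.  The step count is `ceil(t_end/dt)` with `dt`
  shrunk to land exactly on `t_end`.
* Simplex states are renormalised after a step only when the 1-norm
  drifts beyond 1e-12; the drift is tangent to the simplex analytically,
  so this corrects rounding, never dynamics.
* Negative field values beyond −1e-10 raise a stability error (reduce
  `dt`); non-finite values abort immediately.
* Stochastic consistency checks (simulator vs mean field, agent SIR vs
  PDE) use 5 frozen replicate seeds, N between 50 and 2000 agents, and
  horizons of a few time units — sizes at which the whole suite runs in
  well under a minute while the Monte-Carlo bands remain informative.
* The kernel quadrature convergence study uses the triangular profile on
  512 grid points with `ε ∈ {0.2, 0.1, 0.05}`, where the measured
  relative deviation between nonlocal and local right-hand sides shrinks
  at order ≈ ε² as the expansion predicts.

## Known limitations

* One-dimensional structural variables only; interfaces admit `d > 1`
  but nothing above d = 1 is implemented or tested.
* No evolving networks, no sparse-graph/graphon limits, no
  hydrodynamic closures beyond monokinetic, no Fokker–Planck PDE solver.
* The discontinuous argmax dynamics of the social model can in principle
  chatter at ties; the fixed-step integrator does not locate tie-crossing
  events exactly.
* The degenerate local SIR system is intentionally unreliable (see
  above) and guarded accordingly.
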