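# Methods

## Models

**Replicator–mutator with observation-driven fitness.**  The density
ρ_t(x) of a 1-D trait evolves under mutation (the Kolmogorov-forward
operator of the signal SDE, L\*ρ = −(gρ)′ + (Σ/2)ρ″) and replication
proportional to the deviation of the fitness from its population mean.  The
fitness is quadratic in the misfit between the observed feature h(x) and the
time-varying target Ż_t, with a replication weight r > 0 on the individual
misfit and an interaction weight s < r on the covariance-type term coupling
an individual to the population: s > 0 rewards conformity, s < 0 rewards
diversity, s = 0 is a pure log-likelihood (Bayesian) fitness.

**Observation drivers.**  The target Ż_t is the derivative of a
piecewise-linear interpolation of an observation path: on each window
[t_i, t_i + δ_d) it is constant, equal to h(x\*_{t_i}) + Ξ^{1/2}ΔB_i/δ_d,
with the signal sampled at the window's left endpoint.  As δ_d → 0 this
smooth driver converges to the rough path dZ = h(x\*)dt + Ξ^{1/2}dB, and
solutions of the replicator–mutator converge to the *Stratonovich*
interpretation of the corresponding Zakai equation (the Wong–Zakai
phenomenon).  All Brownian increments are generated at the simulation
resolution dt and aggregated per window, so refining δ_d under a fixed seed
reuses one Brownian path, and the smooth and rough drivers can be coupled
exactly.

**Linear-Gaussian closure.**  For g(x) = Gx, h(x) = Hx and a Gaussian
initial law the density stays Gaussian and the flow closes on the moment
equations

    dm = G m dt + (r − s) K (dZ − H m dt),    K = C H' Ξ⁻¹,
    dC/dt = G C + C G' + Σ − r C H' Ξ⁻¹ H C.

Only r enters the covariance; s only steers the mean.  (1, 0) is the
Kalman–Bucy filter; (1+ε, 0) is multiplicative covariance inflation and
(1−2ε, −2ε) additive inflation.

**Misspecification analysis.**  The reference signal carries a constant
drift bias b that the filter's model omits.  With the filter covariance
initialised at its steady state C∞(r), the error ε = m − x\* has stationary
statistics governed by A∞ = G − (r−s)K∞H: squared bias ν∞ = ‖A∞⁻¹b‖², and
MSE E∞ = Tr[(Σ + (r−s)(G−A∞)C∞ − 2A∞⁻¹bb′)X∞] with A∞′X∞ + X∞A∞ + I = 0.
In the scalar case E∞ = −(Σ + (G−A∞)²Ξ/H²)/(2A∞) + (b/A∞)².  Minimising E∞
over the error rate gives a depressed cubic A³ + pA + q = 0 with
p = −(H²Ξ⁻¹Σ + G²) and q = 4b²H²Ξ⁻¹, whose unique negative root A∞\* is
evaluated by the Cardano branch (one real root, τ = q²/4 + p³/27 > 0) or
the k = 2 trigonometric branch (τ < 0), and always cross-checked against a
bracketed bisection root at 1e−8.  From A∞\* follow s_opt(r), the bounds
s_l = −(G+A∞\*)²/(4H²Ξ⁻¹Σ) and s_u = s_opt at y = |G| (zero whenever
G > 0), the one or two optimal r for a given s, and r0_opt =
((A∞\*)² − G²)/(H²Ξ⁻¹Σ) for s = 0.  The *calibrated joint optimum*
additionally solves r − s_opt(r) = A∞\*²(G−A∞\*) / (−A∞\*(H²Ξ⁻¹Σ +
(G−A∞\*)²)/2 + b²H²Ξ⁻¹) by bisection on (0, r0_opt + 1] (tolerance 1e−10)
and is verified a posteriori to satisfy |C∞ − E∞|/E∞ < 1e−6.

## Numerical choices

**Grids and stepping.**  PDE solvers use a uniform grid (default 801
nodes), zero Dirichlet boundaries, central second differences for
diffusion, first-order upwind differences for transport, trapezoid
quadrature for all expectations, and forward Euler (Euler–Maruyama for the
rough driver) in time.  A CFL guard enforces dt ≤ 0.25 dx²/Σ and
dt ≤ 0.5 dx/max|g|.  Every step renormalises the density and accumulates
the log of the removed mass, so unnormalised solutions stay representable
over long horizons; a blow-up detector aborts on non-finite values or
negatives exceeding 1e−6 of the maximum (small Euler negatives are never
silently clipped during stepping).  Upwind transport adds numerical
diffusion of order |g|dx/2; tests that compare grid moments against the
moment ODEs at 1e−3 relative accuracy therefore use 1201-node grids and
mild drift.

**Zakai modes.**  Three reaction coefficients are exposed for the
rough-driver solver, all sharing the noise term (r−s)q h′Ξ⁻¹dZ:
`ito_paper` with c₀ = −(s/2)h′Ξ⁻¹h (the generalised Zakai equation in Itô
form), `stratonovich` with c₀ = ((r−s)² − r)/2 · h′Ξ⁻¹h (the Itô-corrected
form of the Stratonovich equation — the actual smooth-observation limit),
and `ito_naive` with c₀ = −(r/2)h′Ξ⁻¹h (the Stratonovich-form drift with
the noise misread as Itô, kept as the "wrong limit" contender in the
demonstration experiment).  The first two coincide exactly at (r, s) =
(1, 0), where both reduce to the classical Zakai equation; they differ for
general (r, s) unless r − s ∈ {0, 1}, and we deliberately expose both
rather than reconciling them.

**The unnormalised solver and s ≠ 0.**  The linear ("unnormalised") form
integrates μ with reaction coefficient −(r/2)h′Ξ⁻¹h + (r−s)h′Ξ⁻¹Ż.  Its
normalisation equals the replicator–mutator solution exactly when s = 0
(any r); for s ≠ 0 the linear form omits the mean-field coupling
s·h̄·Ξ⁻¹(h(x) − h̄), which does not integrate out, and the two equations
genuinely differ.  Everything downstream that uses the unnormalised form
(the Zakai-limit demonstration) runs at (1, 0), where the identity is
exact; the equivalence test is likewise at s = 0.

**Static-signal demonstration and snapshot times.**  In the frozen-signal
example (g = 0, Σ = 0, h = Hx, x\* ≡ x₀\*), the time-integral of the
smoothed driver telescopes to the rough path at every window knot, so the
replicator–mutator solution *equals* the Stratonovich solution at knots for
every δ_d — the refinement comparison is degenerate there, and what remains
at knots is pure Euler bias (which grows like dt/δ_d).  The L1 distances
are therefore evaluated at interior times (offset 0.3 of a coarse window,
one point per coarse window, averaged), where the piecewise-linear
interpolation error of order √δ_d is visible and shrinks under refinement.
Study conditions: dt = 1e−4, horizon 0.5, δ_d ∈ {500, 100, 20}·dt on a
common Brownian path, 801 nodes on [m₀ − 9√P₀, x₀\* + 4√P₀].

**Ensemble filters.**  All four mean-field variants share the pre-drift
−(s/2)KH(X − m̂)dt and innovation weight (r − s); stochastic variants use
the particle's own innovation (dZ − HX dt) plus an independent perturbation
noise with covariance (r−s)KΞK′ per unit time, deterministic variants use
the averaged innovation (dZ − H(X + m̂)dt/2) and no perturbation noise.
This is the unique coefficient family that (a) reduces to the standard
stochastic/deterministic ensemble Kalman–Bucy filters at (1, 0) and (b)
makes the empirical moments satisfy the (r, s) moment equations as
N → ∞ under Fokker–Planck bookkeeping — the property the covariance-
inflation correspondence rests on.  Gains use the 1/(N−1) empirical
covariance, recomputed every step.  The moment-contract test runs all four
variants at N = 20000, dt = 1e−3, horizon 1, with observations generated
from an unbiased reference: a biased reference gives the innovation an O(1)
mean, which couples to the O(1/N) empirical-covariance bias of the
deterministic variants and contaminates the mean at the 3-standard-error
resolution of the test.

**Error-moment trajectories.**  The bias obeys dE[ε]/dt = A_t E[ε] − b and
the error covariance dP/dt = A_tP + PA_t′ + Σ + (r−s)²KΞK′ with the gain
from the covariance ODE.  The mean-square matrix is formed as
P̃ = P + E[ε]E[ε]′, which makes the bias–variance identity E = Tr(P) + ν
exact at every stored step by construction; a direct Euler integration of
the P̃ ODE is kept as a cross-check at O(dt) tolerance (integrating it
independently cannot preserve the identity beyond O(dt²) per step).  The
Gronwall bound curve uses the estimate Tr[KΞK′] ≤ α(H′Ξ⁻¹H)·‖C‖²_F (the
squared Frobenius norm is required; the unsquared form is not a bound), and
in the scalar case the resulting asymptotic bound is tight.

**Tempering flows.**  The homotopy integrates d(log p) = (W − E_p[W])dt in
log-density space — exact for the pointwise exponential tilt, underflow-safe
for sharp likelihoods, with time-discretisation error entering only through
the evolving mean fitness; 2000–5000 Euler steps reach 1e−4 L1 agreement
with the direct tilt for the likelihoods used in the tests.  The Fisher–Rao
operators follow the boundary convention 0/0 = 0 at nodes where p = 0, and
the metric inverse subtracts ∫φp so its output is an exact tangent vector.
Non-local fitness kernels must be symmetric and are rejected otherwise
(the mean-fitness energy and its Fréchet derivative require symmetry); the
1-D transport velocity is the unique decaying solution
v = −(1/p)∫ˣ(W − E[W])p, obtained by cumulative trapezoid quadrature.

## Synthetic data and study conditions

There is no external data; all inputs are seeded simulations.  Two scalar
benchmark systems are packaged — system 1: G=0.5, H=8.5, Σ=0.8, Ξ=6.3,
b=9.9 (τ > 0); system 2: G=2.5, H=2.9, Σ=18, Ξ=26, b=1.2 (τ < 0) — both
with unstable signal dynamics, plus the frozen-signal example (H=2, Ξ=1,
m₀=0, P₀=0.3, x₀\*=5).  Fixture initial covariances default to the
perfect-model steady state; analyses that require C₀ = C∞(r) set it
internally.  The Monte-Carlo MSE estimator uses N_s = 500 smoothed
observation paths per reference trajectory at dt = 1e−4, δ_d = 1e−3, and
time-averages the squared error over the final unit of time (the mean of a
stationary process).  Because a single reference path leaves an O(1)
fluctuation from the signal noise common to all observation paths,
comparisons against the ensemble-averaged closed form average over 12
independent reference draws and compute the standard error across
references.  Horizons are 3 for system 1 and 1.5 for system 2: the
asymptotic formulas are δ_d → 0 statements, and with an unstable signal the
left-endpoint window sampling lags the reference by ~G·δ_d·|x\*|, which
grows like e^{GT} — the horizon is chosen long relative to the error
relaxation time 1/|A∞| but short enough that this lag stays negligible.

What the generators do *not* emulate: model error beyond a constant bias,
time-varying or state-dependent noise, irregular observation windows,
non-Gaussian initial laws, and multivariate signals in the optimiser (the
closed-form design theory is scalar; matrix inputs are accepted by the
steady-state error functionals via the Lyapunov route, but the optimisers
reject them).  Passing tests therefore certify the internal consistency of
the theory under exactly these idealised conditions, not performance on
real assimilation systems.

## Known limitations

- Explicit (forward-Euler) schemes throughout: stiff settings demand small
  steps; no implicit or spectral options.
- 1-D trait space only for the PDE and transport solvers.
- First-order upwind transport: moment accuracy beyond ~1e−3 requires fine
  grids.
- The optimal-(r, s) theory is scalar; the multivariate design problem is
  out of scope.
- The unnormalised replicator–mutator form is a faithful companion of the
  normalised one only for s = 0 (see above).
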