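# rmfilter

Evolutionary dynamics and sequential Bayesian inference describe the same
mathematics from two directions: a population of trait values adapting to a
fitness landscape (the Crow–Kimura replicator–mutator PDE) and the
conditional density of a hidden diffusion given noisy observations (the
Kushner–Stratonovich / Zakai equations of stochastic filtering).  `rmfilter`
is a toolkit for working on that bridge.  It is aimed at researchers in
filtering, data assimilation and mathematical evolution who want executable,
tested versions of the objects involved:

- **1-D grid solvers** for the replicator–mutator equation
  ∂ρ = L\*ρ + ρ(E_z[f(x,z)] − E[f]) with the time-varying quadratic fitness

  f_t(x, z) = −(r/2)‖h(x) − Ż_t‖²_Ξ + s⟨h(x) − Ż_t, h(z) − Ż_t⟩_Ξ,  r > 0, s < r,

  driven by a *piecewise-smooth* observation derivative Ż_t (constant on
  windows of width δ_d), and for the (modified) Zakai equation driven by the
  rough observation path — in Stratonovich and Itô interpretations, so the
  Wong–Zakai phenomenon (smooth approximations converge to the Stratonovich
  limit) can be demonstrated numerically.
- **Tempering / homotopy flows**: static-data Bayesian inversion as a pure
  replicator flow p_t ∝ e^{tf} p_0, the Fisher–Rao metric operators, the
  gradient-flow identity for the mean-fitness energy
  F(p) = −½∬f(x,z)p(x)p(z), and the equivalent velocity-field particle
  transport.
- **The linear-Gaussian (r,s)-filter**: moment equations
  dm = Gm dt + (r−s)K(dZ − Hm dt), dC/dt = GC + CG' + Σ − rCH'Ξ⁻¹HC
  (Kalman–Bucy at (r,s) = (1,0)), four mean-field ensemble variants, and the
  exact correspondence with covariance inflation — multiplicative inflation
  is (r, s) = (1+ε, 0), additive inflation is (1−2ε, −2ε).
- **Misspecified-filter design**: when the signal carries an unknown
  constant bias b, closed forms for the asymptotic squared bias
  ν∞ = ‖A∞⁻¹b‖², the asymptotic MSE E∞, the MSE-optimal weights s_opt(r)
  and r_opt(s) (via a depressed cubic for the optimal error rate A∞*), and
  the unique *calibrated* pair (r\*, s\*) whose reported covariance C∞
  equals the MSE it actually achieves.

## Worked example

Two scalar benchmark systems ship with the package (`builtin_fixture`).
For system 1 (G=0.5, H=8.5, Σ=0.8, Ξ=6.3, bias b=9.9):

```python
from rmfilter import builtin_fixture
from rmfilter import misspec as M

s1 = builtin_fixture("system1")
rep = M.optima_report(s1)
print(f"perfect-model covariance   C_hat  = {rep.C_hat_inf:.4f}")
print(f"MSE-optimal r at s=0       r0_opt = {rep.r0_opt:.2f}")
print(f"covariance there           C_inf  = {rep.C_inf_r0:.4f}  (ratio {rep.overconfidence_ratio:.3f})")
print(f"calibrated joint optimum   (r*, s*) = ({rep.r_star:.3f}, {rep.s_star:.3f})")
print(f"minimal asymptotic MSE     E_inf  = {rep.E_inf_opt:.4f}")
```

prints

```
perfect-model covariance   C_hat  = 0.3113
MSE-optimal r at s=0       r0_opt = 30.35
covariance there           C_inf  = 0.0494  (ratio 0.159)
calibrated joint optimum   (r*, s*) = (0.129, -1.177)
minimal asymptotic MSE     E_inf  = 1.1477
```

Read: a pure multiplicative-inflation filter tuned for MSE (s=0, r≈30.4)
reports a covariance of 0.049 — six times *smaller* than the perfect-model
filter's 0.311, i.e. it is badly overconfident while its actual error is
much larger.  Switching on the non-local fitness (s\* ≈ −1.18, a
*diversity-rewarding* interaction) with r\* ≈ 0.13 achieves the same minimal
MSE ≈ 1.148 while reporting a covariance exactly equal to it — honest
uncertainty quantification under misspecification.

The Monte-Carlo counterpart (500 smoothed observation paths per reference
trajectory, forward-Euler at dt = 1e−4, δ_d = 1e−3):

```python
from rmfilter import FitnessParams, MCConfig, empirical_mse
res = empirical_mse(s1, FitnessParams(rep.r_star, rep.s_star),
                    MCConfig(N_s=500, T=3.0, seed=0),
                    average_reference=True, n_reference=12)
print(f"MC MSE = {res.terminal:.4f} +/- {res.terminal_se:.4f}")
# MC MSE = 1.1638 +/- 0.0127   (closed form: 1.1477)
```

A command-line interface mirrors the library
(`rmfilter simulate|pde|temper|filter|misspec|mse|sweep|fig1`); e.g.
`rmfilter misspec --fixture system1 --report optima --out out/` writes the
report above as JSON.

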