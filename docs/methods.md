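# Methods

## Model

A single-compartment lung is driven at constant pressure `Pd` during
inspiration (`0 ≤ t ≤ tj`) and released (`Paw = 0`) during expiration
(`tj ≤ t ≤ tb`). With resistive pressure `R·DV` and elastic pressure `V/C`,
the airway balance gives one first-order linear equation per phase:

```
R · D^α V + V/C + Pm = Paw .
```

`D^α` is one of three local (memoryless) derivatives: the proportional
derivative `(1−α)f + αf′` of PD-controller type with the linear gain pair
`κ₁ = 1−α, κ₀ = α`; the conformable derivative `t^{1−α}f′`; and the
truncated-M derivative `t^{1−α}f′/Γ(β+1)`. All three reduce to `f′` at
`α = 1` (with `β = 1` for the M family, since `Γ(2) = 1`); the proportional
family additionally reduces to the identity at `α = 0`, which the other two
do not. These equivalence forms, valid for differentiable functions, are
the only evaluation path in the package — the underlying ε-limit
definitions are numerically fragile and are kept solely as Richardson-
extrapolated oracles in the test suite.

## Closed forms

Every phase solution is the exponential

```
V(t) = V∞ + (V₀ − V∞) · exp(−λ (w(t) − w(t₀)))
```

anchored at `(t₀, V₀)`. Proportional family: `w(t) = t`,
`V∞ = C·K/(1+CR−αCR)`, `λ = (1+CR−αCR)/(αCR)`, obtained by the
proportional Laplace transform and partial-fraction inversion of the
single-pole rational transform (the package inverts it with
`scipy.signal.residue` and cross-checks the pole/residue against the
hand-derived expressions). Conformable/truncated-M: `V∞ = C·K`,
`λ = 1/(CR)` or `Γ(β+1)/(CR)`, and warped time `w(t) = sgn(t−t₀)|t−t₀|^α/α`.
`K = Pd − Pm` during inspiration, `−Pm` during expiration.

**Signed-power branch.** The end-of-breath anchored expiration solutions
raise `(t − tb)` to the power `α` with a *negative* base everywhere inside
the breath. The package uses the odd real branch `sgn(x)|x|^α`; it is the
unique continuous choice that recovers the classical exponential
`CPm(e^{(tb−t)/RC} − 1)` at `α = 1` and produces decaying expiration
curves. The shifted dilation `|t − t₀|^{1−α}` is used consistently in the
governing equation of every anchored solution, so each closed form
satisfies its own equation identically (residuals at machine precision,
asserted to < 1e−8 cm H₂O in tests).

**Corrected switch-anchored inspiration.** The traditional printed
expressions for the inspiration solution anchored at `V(tj) = VT` evaluate
to `VT − 2V∞` (proportional) or `VT + 2V∞` (conformable/M) at `t = tj`,
i.e. they violate the very anchor they are solved for — verified
symbolically in the test suite. The package implements the corrected form
`V∞ + (VT − V∞)e^{−λΔw}`, which anchors exactly, and keeps the verbatim
expressions behind `printed_tidal_inspiration` for documentation tests
only. The switch-anchored *expiration* expression is algebraically correct
as printed and is implemented equivalently in the shared exponential form.

## Residual pressure Pm

Two policies are provided because the choice is genuinely open:

* `classical_formula` (default for figure-style output):
  `Pm = Pd(e^{tj/RC}−1)/(e^{tb/RC}−1)`, the α-independent classical value.
  Reference figures use it at every order, which leaves
  `Vi(tj) ≠ Ve(tj)` for `α < 1`; waveform assembly records that jump rather
  than hiding it.
* `self_consistent` (default for waveform assembly): the per-family value
  enforcing `Vi(tj) = Ve(tj)`, hence `Ve(tb) = 0`:
  `Pd(e^{λtj}−1)/(e^{λtb}−1)` for the proportional family and
  `Pd(1−e^{−u})/(e^{v}−e^{−u})` with `u = λ·tj^α/α`,
  `v = λ·(tb−tj)^α/α` for the warped families. Both reduce to the classical
  formula at `α = 1` (asserted to 1e−12 over randomized parameters).

Tidal volume defaults to `VT = Vi(tj)` of the same family/order/Pm — no
external value exists for it. Mean alveolar pressure is
`(1/(C·tj))∫₀^{tj}Vi dt + Pm` by adaptive quadrature, cross-checked against
the closed-form antiderivative for the unwarped families (agreement 1e−9).

## Solution methods

**Proportional Laplace transform.** The n-fold proportional derivative
expands binomially over classical derivatives with weights
`C(n,r)α^{n−r}(1−α)^r` (summing to 1), giving the transform rule
`(αs+1−α)^n Φ(s) − Σ_k B_k(s) φ^{(k)}(0)` with
`B_k(s) = α^{k+1} Σ_r C(n,r)(αs)^{n−1−k−r}(1−α)^r`. Polynomials are
ascending coefficient tuples; with `fractions.Fraction` orders the whole
algebra is exact, and the direct rule is asserted equal to the n-fold
composition of the first-order rule for `n ≤ 6` over a set of rational
orders. Runtime solvers use floating point.

**Proportional variation of parameters.** For
`m D^α D^α y + 2b D^α y + k y = g`, substituting `y = e^{ρt}` with
`μ = (1−α) + αρ` reduces the homogeneous problem to the ordinary auxiliary
polynomial `mμ² + 2bμ + k = 0`; the sign of `mk − b²` selects overdamped,
critical or underdamped bases (the underdamped pair
`e^{μt}cos(ω_α t), e^{μt}sin(ω_α t)` carries `μ = (−b−(1−α)m)/(mα)`,
`ω_α = √(mk−b²)/(mα)` — both the decay and the frequency are dilated by
`1/α`, the form under which the p-Wronskian closed form
`(√(mk−b²)/m)e^{2(−b−m+αm)t/(mα)}` is exact). With the linear gains the
p-Wronskian equals `α ×` the classical Wronskian (the `(1−α)` cross terms
cancel), and the coefficient derivatives are
`γ₁′ = −y₂g/(α²W)`, `γ₂′ = y₁g/(α²W)`; they are integrated by adaptive
8th-order Runge-Kutta with dense output (rtol 1e−11), which makes the
particular solution cheaply evaluable on whole grids. Initial data are
`(y(t₀), D^α y(t₀))` — using the proportional-derivative value keeps the
`α = 1` limit the standard IVP. Only the order-2α path is implemented; the
general order-nα method is out of scope.

## Independent oracle

Each model phase is reformulated as a classical ODE by substituting the
equivalence forms: `V′ = (K − V/C − R(1−α)V)/(αR)` (proportional) or
`V′ = Γ(β+1)(K − V/C)|t−t₀|^{α−1}/R` (warped families). The warped
coefficient diverges at the anchor while the solution stays finite, so
integration runs in warped time `u = sgn(t−t₀)|t−t₀|^α/α`, where the
equation is regular. End-anchored expiration requires integrating *against*
exponentially growing dynamics (amplification up to ~1e19 at `α = 0.25`);
any fixed absolute tolerance is then amplified into garbage, so backward
sweeps run under essentially pure relative error control (atol 1e−60,
rtol 1e−12), which is well-conditioned for a growing mode. Forward sweeps
use rtol 1e−12 / atol 1e−14. Closed forms agree with the oracle to better
than 1e−11 relative; the test suites assert 1e−6.

## Numerical choices

* Quadrature (proportional integral/exponential, mean alveolar pressure):
  `scipy.integrate.quad`, abs/rel tolerance 1e−10 to 1e−12.
* Truncated Mittag-Leffler: partial sum, default truncation index 40 with
  a |term| < 1e−16 stopping rule.
* Wronskian magnitudes below 1e−14 raise a degenerate-basis error.
* Residual grids are uniform and include phase endpoints; the closed forms
  are finite at the warp anchor even where the ODE coefficient is singular,
  because the dilation cancels analytically in `PhaseSolution.local_derivative`.
* Problem sizes: residual checks use 200-point grids per phase, oracle
  comparisons 60-point grids — both chosen as comfortably resolving
  trajectories whose fastest rate is `λ ≤ 23 s⁻¹`.

## What the parameter grids emulate, and limits

The shipped defaults (`R = 10`, `C = 0.02`, `Pd = 20`, `tj = 1`, `tb = 3`)
are a standard adult pressure-controlled ventilation setting; the α grids
(0.25–1) and β grids (0.5–1.5) span the figure settings of the source
model. The model itself is deliberately minimal: one compartment, constant
compliance and resistance, constant `Pm` (no PEEP dynamics), no patient
effort, and multi-breath assembly simply repeats the single-breath closed
forms from the previous end volume. Passing tests demonstrate internal
consistency of the mathematics — closed forms solving their equations,
limits and transforms agreeing — not clinical fidelity; no patient data
enters anywhere.
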