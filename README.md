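# fracvent

Closed-form models of pressure–volume controlled mechanical ventilation
under **local fractional derivatives**, with the solution machinery they
need and an independent numerical oracle that checks every formula.

## The problem

A ventilated lung is commonly modelled as a single compartment obeying a
pressure balance at the airway,

```
P_l + P_k + P_m = P_aw,      P_l = R · dV/dt,   P_k = V / C,
```

where `R` is the airway resistance (cm H₂O·s/L), `C` the lung compliance
(L/cm H₂O), `P_m` a constant residual pressure, and `P_aw` the applied
airway pressure — the driving pressure `P_d` during inspiration
(`0 ≤ t ≤ t_j`) and `0` during expiration (`t_j ≤ t ≤ t_b`). `fracvent`
generalizes the time derivative to three *memoryless* derivatives of
non-integer order `α`:

| family | `D^α f` (differentiable `f`) | α = 1 limit |
|---|---|---|
| proportional | `(1−α) f + α f′` | `f′` |
| conformable | `t^{1−α} f′(t)` | `f′` |
| truncated-M | `t^{1−α} f′(t) / Γ(β+1)` | `f′` (at β = 1) |

Every breath phase then solves in the shared form

```
V(t) = V∞ + (V₀ − V∞) · exp( −λ · (w(t) − w(t₀)) ),
```

with family-specific asymptote `V∞`, rate `λ` and time warp `w` (identity
for the proportional family, signed power `sgn(t−t₀)|t−t₀|^α/α` for the
other two). For the proportional family,
`V∞ = C·K/(1 + CR − αCR)` and `λ = (1 + CR − αCR)/(αCR)` with
`K = P_d − P_m` (inspiration) or `−P_m` (expiration).

Beyond the lung model the package implements the two general solution
methods behind it: the **proportional Laplace transform** (the transform
rule for the n-fold proportional derivative, exact in rational arithmetic)
and **proportional variation of parameters** for 2α-order equations,
applied to the damped mass–spring system
`m D^α D^α y + 2b D^α y + k y = g(t)`.

Intended users: researchers in fractional-order modelling and respiratory
mechanics who want verified closed forms, not just plots.

## Worked example

```python
from fracvent import (DerivativeSpec, ResidualPressurePolicy, VentParams,
                      breath_waveform, mean_alveolar_pressure)

params = VentParams()                   # R=10, C=0.02, Pd=20, tj=1, tb=3
spec = DerivativeSpec(family="proportional", alpha=0.8)
wf = breath_waveform(params, spec,
                     policy=ResidualPressurePolicy(mode="self_consistent"))
print(wf.metadata["Pm"], wf.metadata["VT"])
print(mean_alveolar_pressure(params, wf.metadata["Pm"], spec))
```

Running `python examples/breath_waveform.py` (same computation) prints:

```
residual pressure Pm   = 4.513862e-05 cm H2O   (offset that empties the lung by tb)
tidal volume VT        = 0.384036 L          (volume at the tj switch)
mean alveolar pressure = 16.2766 cm H2O    (average elastic pressure + Pm)
V(0) = 0.00e+00 L,  V(tb) = -4.24e-22 L  (both breath boundaries)
max governing-equation residual = 6.53e-15 cm H2O  (closed forms solve the model)
```

`Pm` is the constant offset that makes the lung empty exactly at the end of
the breath; `VT` is the tidal volume (lung volume at the inspiration →
expiration switch); the residual line confirms the closed-form trajectory
satisfies the governing equation to machine precision.

More examples live in `examples/` (cross-family comparison, the mass–spring
solver, the transform-rule algebra), and a thin CLI wraps the library:

```
fracvent simulate --family proportional --alpha 0.8 --out out/
fracvent figures  --family all --alpha 0.9 --beta 0.8 --out out/
fracvent fixtures --out fixtures/
```

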