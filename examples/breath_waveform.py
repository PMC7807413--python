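"""Build one ventilator breath under the proportional derivative and print
its clinical summary numbers.

The lung (R = 10 cm H2O.s/L, C = 0.02 L/cm H2O) is driven at Pd = 20 cm H2O
for tj = 1 s and then released until tb = 3 s. The residual pressure Pm is
chosen self-consistently so the breath closes (V(tb) = 0) at the chosen
derivative order.
"""

import numpy as np

from fracvent import (
    DerivativeSpec,
    ResidualPressurePolicy,
    VentParams,
    breath_waveform,
    mean_alveolar_pressure,
    residual_check,
)

params = VentParams()
spec = DerivativeSpec(family="proportional", alpha=0.8)
policy = ResidualPressurePolicy(mode="self_consistent")

wf = breath_waveform(params, spec, policy=policy, n_points=200)
pm = wf.metadata["Pm"]
vt = wf.metadata["VT"]
pma = mean_alveolar_pressure(params, pm, spec)
worst = max(
    residual_check(sol, params, pm, spec, sol.phase, np.linspace(lo, hi, 200))
    for sol, lo, hi in wf.segments
)

print(f"residual pressure Pm   = {pm:.6e} cm H2O   (offset that empties the lung by tb)")
print(f"tidal volume VT        = {vt:.6f} L          (volume at the tj switch)")
print(f"mean alveolar pressure = {pma:.4f} cm H2O    (average elastic pressure + Pm)")
print(f"V(0) = {wf.volumes[0]:.2e} L,  V(tb) = {wf.volumes[-1]:.2e} L  (both breath boundaries)")
print(f"max governing-equation residual = {worst:.2e} cm H2O  (closed forms solve the model)")
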