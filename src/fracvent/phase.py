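"""Closed-form single-phase volume trajectories.

Every phase of the ventilation model — inspiration or expiration, any
derivative family — has a solution of the shared shape

    V(t) = V_inf + (V0 - V_inf) * exp(-rate * (w(t) - w(t0))),

where ``w`` is a family-dependent time warp anchored at ``t0``:

* classical / proportional:  w(t) = t
* conformable / truncated-M: w(t) = sgn(t - t0) |t - t0|^alpha / alpha

The signed-power branch is deliberate: the tb-anchored expiration solution
raises (t - tb) to the power alpha with a negative base on the breath, and
the odd real branch is the unique continuous choice that recovers the
classical exponential at alpha = 1 and yields decaying expiration curves.
For the truncated-M family the Gamma(beta + 1) factor is carried in
``rate``, not in the warp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from fracvent.local_calculus import DerivativeSpec, Family, signed_power

__all__ = ["PhaseSolution"]


@dataclass(frozen=True)
class PhaseSolution:
    """One breath phase in closed form: V(t) = V_inf + (V0 - V_inf) e^{-rate (w(t)-w(t0))}.

    Attributes
    ----------
    spec:
        Derivative family and orders the solution was built for.
    phase:
        ``"inspiration"`` or ``"expiration"`` (decides the airway pressure
        in residual checks).
    V_inf:
        Asymptotic volume of the phase (L). May be negative for expiration.
    V0, t0:
        Anchor: the solution passes through (t0, V0) exactly. For the
        conformable/truncated-M families ``t0`` is also the warp origin.
    rate:
        Decay rate; 1/s for classical/proportional, 1/s^alpha-scaled for
        the warped families (Gamma(beta+1)/(CR) for truncated-M).
    """

    spec: DerivativeSpec
    phase: Literal["inspiration", "expiration"]
    V_inf: float
    V0: float
    t0: float
    rate: float
    meta: dict = field(default_factory=dict, compare=False)

    # -- time warp ---------------------------------------------------------

    @property
    def warped(self) -> bool:
        return self.spec.family in (Family.CONFORMABLE, Family.TRUNCATED_M)

    def warp(self, t):
        """w(t): identity for classical/proportional, signed power otherwise."""
        if not self.warped:
            return np.asarray(t, dtype=float) if np.ndim(t) else float(t)
        return signed_power(np.asarray(t, dtype=float) - self.t0, self.spec.alpha) / self.spec.alpha

    def _delta_w(self, t):
        if self.warped:
            return self.warp(t)  # w(t0) = 0 by construction
        return np.asarray(t, dtype=float) - self.t0

    # -- evaluation --------------------------------------------------------

    def __call__(self, t):
        """Volume at time(s) ``t`` (L)."""
        dw = self._delta_w(t)
        out = self.V_inf + (self.V0 - self.V_inf) * np.exp(-self.rate * dw)
        return out if np.ndim(out) else float(out)

    def derivative(self, t):
        """Classical dV/dt. Singular like |t - t0|^(alpha-1) at the warp origin."""
        dw = self._delta_w(t)
        core = -self.rate * (self.V0 - self.V_inf) * np.exp(-self.rate * dw)
        if self.warped:
            core = core * np.abs(np.asarray(t, dtype=float) - self.t0) ** (self.spec.alpha - 1.0)
        return core if np.ndim(core) else float(core)

    def local_derivative(self, t):
        """The family derivative appearing in the governing equation.

        For the conformable/truncated-M families the dilation factor
        |t - t0|^(1-alpha) cancels the singular factor in dV/dt analytically,
        so the result is finite everywhere including the warp origin.
        """
        fam = self.spec.family
        dw = self._delta_w(t)
        decay = np.exp(-self.rate * dw)
        if fam is Family.CLASSICAL:
            out = -self.rate * (self.V0 - self.V_inf) * decay
        elif fam is Family.PROPORTIONAL:
            a = self.spec.alpha
            out = (1.0 - a) * self.__call__(t) + a * (
                -self.rate * (self.V0 - self.V_inf) * decay
            )
        else:
            out = -self.rate * (self.V0 - self.V_inf) * decay / self.spec.gamma_beta
        return out if np.ndim(out) else float(out)
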