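"""Independent numerical verification of the closed-form solutions.

Each local-derivative model equation is rewritten as a classical first-order
ODE by substituting the differentiable-function equivalence form of the
derivative:

* proportional:  R[(1-a)V + a V'] + V/C = Paw - Pm
                 =>  V' = (K - V/C - R(1-a)V) / (a R)
* conformable:   R |t - t0|^(1-a) V' + V/C = Paw - Pm
                 =>  V' = (K - V/C) |t - t0|^(a-1) / R
* truncated-M:   as conformable times Gamma(b+1)

with K = Pd - Pm (inspiration) or -Pm (expiration) and t0 the warp anchor
(0 for start-anchored phases; tj or tb for switch/end-anchored ones, where
the dilation follows the signed-power branch).

The conformable/M right-hand side diverges like |t - t0|^(a-1) at the
anchor although the solution itself stays finite; integration is therefore
performed in the warped time u = sgn(t-t0)|t-t0|^a / a, in which the
equation is the *regular* linear ODE dV/du = (K - V/C) Gamma(b+1) / R.

The oracle never touches the closed forms: it is adaptive high-order
Runge-Kutta on the reformulated equations, and agreement with the
analytic solutions is the package's main verification identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import integrate

from fracvent.local_calculus import DerivativeSpec, Family, signed_power
from fracvent.phase import PhaseSolution
from fracvent.vent_model import VentParams

__all__ = [
    "ReformulatedODE",
    "classical_reformulation",
    "integrate_oracle",
    "residual_check",
]

# Backward sweeps (end-anchored expiration) integrate against exponential
# growth; tight local tolerances keep the amplified global error small.
_IVP_RTOL = 1e-12
_IVP_ATOL = 1e-14


@dataclass(frozen=True)
class ReformulatedODE:
    """A model phase as a classical ODE, with its warped-time twin.

    ``rhs(t, V)`` is dV/dt in physical time (singular at the anchor for the
    warped families at alpha < 1); ``warped_rhs(u, V)`` is dV/du in warped
    time where the equation is regular. ``warp`` maps physical to warped
    time and is the identity for the unwarped families.
    """

    rhs: Callable[[float, float], float]
    domain: tuple[float, float]
    spec: DerivativeSpec
    anchor: float = 0.0
    warped_rhs: Callable[[float, float], float] | None = field(default=None, repr=False)
    note: str = ""

    @property
    def warped(self) -> bool:
        return self.warped_rhs is not None

    def warp(self, t):
        if not self.warped:
            return np.asarray(t, dtype=float)
        return signed_power(np.asarray(t, dtype=float) - self.anchor, self.spec.alpha) / self.spec.alpha


def classical_reformulation(
    params: VentParams,
    Pm: float,
    spec: DerivativeSpec,
    phase: Literal["inspiration", "expiration"],
    anchor: float | None = None,
) -> ReformulatedODE:
    """Rewrite one model phase as a classical ODE (see module docstring).

    ``anchor`` is the warp origin for the conformable/M families; it
    defaults to 0 for inspiration and tb for expiration (the end-of-breath
    anchored form). Pass tj for the switch-anchored solutions.
    """
    if phase not in ("inspiration", "expiration"):
        raise ValueError(f"unknown phase {phase!r}")
    K = (params.Pd - Pm) if phase == "inspiration" else -Pm
    R, C = params.R, params.C
    fam = spec.family

    if fam in (Family.CLASSICAL, Family.PROPORTIONAL):
        a = spec.alpha if fam is Family.PROPORTIONAL else 1.0

        def rhs(t, V):
            return (K - V / C - R * (1.0 - a) * V) / (a * R)

        return ReformulatedODE(
            rhs=rhs,
            domain=(-math.inf, math.inf),
            spec=spec,
            anchor=0.0,
            note="regular everywhere; fixed point at V = CK/(1 + CR - a CR)",
        )

    t0 = anchor if anchor is not None else (0.0 if phase == "inspiration" else params.tb)
    a = spec.alpha
    g = spec.gamma_beta

    def rhs(t, V):
        return g * (K - V / C) * abs(t - t0) ** (a - 1.0) / R

    def warped_rhs(u, V):
        return g * (K - V / C) / R

    return ReformulatedODE(
        rhs=rhs,
        domain=(-math.inf, math.inf),
        spec=spec,
        anchor=t0,
        warped_rhs=warped_rhs,
        note=(
            f"|t - {t0}|^(alpha-1) coefficient diverges at the anchor for alpha < 1; "
            "integrate in warped time u = sgn(t-t0)|t-t0|^alpha / alpha"
        ),
    )


def _sweep(f, span, V0, atol):
    # explicit first step: scipy's automatic choice divides by the error
    # scale, which overflows under the near-zero atol of backward sweeps
    sol = integrate.solve_ivp(
        f, span, [V0], method="DOP853", rtol=_IVP_RTOL, atol=atol,
        first_step=abs(span[1] - span[0]) / 1024.0, dense_output=True,
    )
    if not sol.success:
        raise ArithmeticError(f"oracle integration failed: {sol.message}")
    return sol.sol


def integrate_oracle(ode: ReformulatedODE, t0: float, V0: float, t_grid) -> np.ndarray:
    """Integrate the reformulated ODE from (t0, V0) onto ``t_grid``.

    Warped families are integrated in warped time, where the equation is
    regular, so grids may include the anchor itself.

    Grid points *before* the start time (the end-of-breath anchored
    expiration) are reached by integrating against exponentially growing
    dynamics: for small alpha the amplification over the phase can exceed
    1e19, so any fixed absolute tolerance is amplified into garbage. The
    backward sweep therefore runs under essentially pure *relative* error
    control (atol far below any representable volume), which is
    well-conditioned for a growing mode.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    x_grid = np.asarray(ode.warp(t_grid), dtype=float)
    x0 = float(ode.warp(t0))
    f = ode.warped_rhs if ode.warped else ode.rhs
    out = np.empty_like(x_grid)

    fwd = x_grid >= x0
    if fwd.any():
        hi = float(np.max(x_grid[fwd]))
        if hi == x0:
            out[fwd] = V0
        else:
            dense = _sweep(f, (x0, hi), V0, atol=_IVP_ATOL)
            out[fwd] = dense(x_grid[fwd])[0]
            out[x_grid == x0] = V0

    bwd = ~fwd
    if bwd.any():
        lo = float(np.min(x_grid[bwd]))
        dense = _sweep(f, (x0, lo), V0, atol=1e-60)
        out[bwd] = dense(x_grid[bwd])[0]
    return out


def residual_check(
    solution,
    params: VentParams,
    Pm: float,
    spec: DerivativeSpec,
    phase: Literal["inspiration", "expiration"],
    t_grid,
    anchor: float | None = None,
    fprime: Callable[[float], float] | None = None,
) -> float:
    """Max governing-equation residual |R D^a V + V/C + Pm - Paw| on the grid.

    ``solution`` may be a :class:`PhaseSolution` (analytic derivative, the
    anchor is taken from it) or any callable V(t) (then ``fprime`` supplies
    V' analytically, or a central difference is used, and ``anchor`` sets the
    warp origin of the conformable/M dilation).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    Paw = params.Pd if phase == "inspiration" else 0.0

    if isinstance(solution, PhaseSolution):
        dV = np.asarray(solution.local_derivative(t_grid))
        V = np.asarray(solution(t_grid))
        return float(np.max(np.abs(params.R * dV + V / params.C + Pm - Paw)))

    t0 = anchor if anchor is not None else (0.0 if phase == "inspiration" else params.tb)
    if fprime is None:
        h = 1e-6
        fprime = lambda t: (
            -solution(t + 2 * h) + 8 * solution(t + h) - 8 * solution(t - h) + solution(t - 2 * h)
        ) / (12 * h)
    V = np.array([solution(t) for t in np.atleast_1d(t_grid)])
    dv = np.array([fprime(t) for t in np.atleast_1d(t_grid)])
    fam = spec.family
    if fam is Family.CLASSICAL:
        dV = dv
    elif fam is Family.PROPORTIONAL:
        dV = (1.0 - spec.alpha) * V + spec.alpha * dv
    else:
        dV = np.abs(t_grid - t0) ** (1.0 - spec.alpha) * dv / spec.gamma_beta
    return float(np.max(np.abs(params.R * dV + V / params.C + Pm - Paw)))
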