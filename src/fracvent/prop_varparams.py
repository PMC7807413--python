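"""Proportional variation of parameters for 2-alpha-order linear equations.

Solves the damped mass-spring equation under the proportional derivative,

    m D^a D^a y + 2 b D^a y + k y = g(t),

by the classical recipe lifted to the proportional calculus. Substituting
y = e^{rho t} and writing mu = (1 - a) + a rho turns the homogeneous
equation into the ordinary auxiliary polynomial m mu^2 + 2 b mu + k = 0,
whose discriminant sign classifies the three damping cases. The particular
solution is y_p = gamma1 y1 + gamma2 y2 with

    gamma1' = -y2 g / (a^2 W),   gamma2' = y1 g / (a^2 W),

W the *classical* Wronskian of the basis (with linear gains the proportional
Wronskian is simply a W, the (1 - a) cross terms cancelling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate

from fracvent.local_calculus import DerivativeSpec, Family, eval_local_derivative

__all__ = [
    "MassSpringParams",
    "HomogeneousBasis",
    "ParticularSolution",
    "homogeneous_basis",
    "p_wronskian",
    "variation_of_parameters_particular",
    "solve_mass_spring",
]

_WRONSKIAN_FLOOR = 1e-14


@dataclass(frozen=True)
class MassSpringParams:
    """Damped mass-spring system m D^a D^a y + 2b D^a y + k y = g.

    ``b`` is *half* the damping constant (the equation carries 2b). The sign
    of m k - b^2 classifies the damping: negative -> overdamped, zero ->
    critically damped, positive -> underdamped.
    """

    m: float
    b: float
    k: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.m <= 0 or self.b <= 0 or self.k <= 0:
            raise ValueError("m, b, k must all be positive")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")

    @property
    def case(self) -> str:
        d = self.m * self.k - self.b**2
        if d < 0:
            return "overdamped"
        if d == 0:
            return "critical"
        return "underdamped"


@dataclass(frozen=True)
class HomogeneousBasis:
    """Fundamental pair for the homogeneous equation, with derivatives.

    ``y1, y2`` are the basis functions, ``dy1, dy2`` their classical first
    derivatives and ``ddy1, ddy2`` the second derivatives (all analytic); the
    proportional derivatives follow as (1 - a) y + a y'.
    """

    case: str
    alpha: float
    y1: Callable[[float], float]
    y2: Callable[[float], float]
    dy1: Callable[[float], float]
    dy2: Callable[[float], float]
    ddy1: Callable[[float], float] = field(repr=False, default=None)
    ddy2: Callable[[float], float] = field(repr=False, default=None)

    def prop_d(self, which: int, t: float) -> float:
        """Proportional derivative of basis function 1 or 2 at t."""
        a = self.alpha
        y, dy = (self.y1, self.dy1) if which == 1 else (self.y2, self.dy2)
        return (1.0 - a) * y(t) + a * dy(t)

    def classical_wronskian(self, t: float) -> float:
        return self.y1(t) * self.dy2(t) - self.y2(t) * self.dy1(t)


def homogeneous_basis(params: MassSpringParams) -> HomogeneousBasis:
    """Case-appropriate fundamental pair of the homogeneous equation.

    With mu_pm = (-b +- sqrt(b^2 - mk)) / m the roots of the auxiliary
    polynomial, the basis exponents are rho_pm = (mu_pm - (1 - a)) / a:

    * overdamped:   e^{rho_+ t},  e^{rho_- t}
    * critical:     e^{rho t},    t e^{rho t}
    * underdamped:  e^{mu t} cos(w t),  e^{mu t} sin(w t)
      with mu = (-b - (1-a) m)/(m a) and w = sqrt(mk - b^2)/(m a);
      both the decay and the angular frequency carry the 1/a dilation.
    """
    m, b, k, a = params.m, params.b, params.k, params.alpha
    disc = b * b - m * k
    if disc > 0:  # overdamped
        sq = math.sqrt(disc)
        rp = ((-b + sq) / m - (1.0 - a)) / a
        rm = ((-b - sq) / m - (1.0 - a)) / a
        return HomogeneousBasis(
            case="overdamped",
            alpha=a,
            y1=lambda t: np.exp(rp * t),
            y2=lambda t: np.exp(rm * t),
            dy1=lambda t: rp * np.exp(rp * t),
            dy2=lambda t: rm * np.exp(rm * t),
            ddy1=lambda t: rp * rp * np.exp(rp * t),
            ddy2=lambda t: rm * rm * np.exp(rm * t),
        )
    if disc == 0:  # critically damped
        rho = (-b / m - (1.0 - a)) / a
        return HomogeneousBasis(
            case="critical",
            alpha=a,
            y1=lambda t: np.exp(rho * t),
            y2=lambda t: t * np.exp(rho * t),
            dy1=lambda t: rho * np.exp(rho * t),
            dy2=lambda t: (1.0 + rho * t) * np.exp(rho * t),
            ddy1=lambda t: rho * rho * np.exp(rho * t),
            ddy2=lambda t: rho * (2.0 + rho * t) * np.exp(rho * t),
        )
    # underdamped
    mu = (-b - (1.0 - a) * m) / (m * a)
    w = math.sqrt(m * k - b * b) / (m * a)
    return HomogeneousBasis(
        case="underdamped",
        alpha=a,
        y1=lambda t: np.exp(mu * t) * np.cos(w * t),
        y2=lambda t: np.exp(mu * t) * np.sin(w * t),
        dy1=lambda t: np.exp(mu * t) * (mu * np.cos(w * t) - w * np.sin(w * t)),
        dy2=lambda t: np.exp(mu * t) * (mu * np.sin(w * t) + w * np.cos(w * t)),
        ddy1=lambda t: np.exp(mu * t)
        * ((mu * mu - w * w) * np.cos(w * t) - 2 * mu * w * np.sin(w * t)),
        ddy2=lambda t: np.exp(mu * t)
        * ((mu * mu - w * w) * np.sin(w * t) + 2 * mu * w * np.cos(w * t)),
    )


def p_wronskian(
    y1: Callable[[float], float],
    y2: Callable[[float], float],
    alpha: float,
    t: float,
    dy1: Callable[[float], float] | None = None,
    dy2: Callable[[float], float] | None = None,
) -> float:
    """Proportional Wronskian y1 D^a y2 - y2 D^a y1.

    With linear gains the (1 - a) y1 y2 cross terms cancel, leaving
    a * (y1 y2' - y2 y1'): alpha times the classical Wronskian.
    """
    spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=alpha)
    d2 = eval_local_derivative(y2, spec, t, fprime=dy2)
    d1 = eval_local_derivative(y1, spec, t, fprime=dy1)
    return y1(t) * d2 - y2(t) * d1


@dataclass(frozen=True)
class ParticularSolution:
    """Particular solution y_p = gamma1 y1 + gamma2 y2 with dense coefficients.

    ``gamma1`` and ``gamma2`` are cubic-spline-accurate dense outputs of the
    quadrature ODE started at t0 (where both vanish, so y_p(t0) = 0 and
    y_p'(t0) = 0 by the variation-of-parameters constraint).
    """

    basis: HomogeneousBasis
    g: Callable[[float], float] = field(repr=False)
    t0: float = 0.0
    _dense: object = field(repr=False, default=None)

    def gammas(self, t):
        vals = self._dense(np.atleast_1d(np.asarray(t, dtype=float)))
        g1, g2 = vals[0], vals[1]
        if np.ndim(t) == 0:
            return float(g1[0]), float(g2[0])
        return g1, g2

    def gamma_primes(self, t: float) -> tuple[float, float]:
        b = self.basis
        a2 = b.alpha**2
        W = b.classical_wronskian(t)
        if abs(W) < _WRONSKIAN_FLOOR:
            raise ArithmeticError(f"classical Wronskian ~ 0 at t={t}; basis degenerate")
        gt = self.g(t)
        return -b.y2(t) * gt / (a2 * W), b.y1(t) * gt / (a2 * W)

    def __call__(self, t):
        g1, g2 = self.gammas(t)
        t_arr = np.asarray(t, dtype=float)
        out = g1 * self.basis.y1(t_arr) + g2 * self.basis.y2(t_arr)
        return out if np.ndim(out) else float(out)

    def derivative(self, t: float) -> float:
        # gamma1' y1 + gamma2' y2 = 0 by construction, so only these survive
        g1, g2 = self.gammas(t)
        return g1 * self.basis.dy1(t) + g2 * self.basis.dy2(t)

    def second_derivative(self, t: float) -> float:
        g1, g2 = self.gammas(t)
        g1p, g2p = self.gamma_primes(t)
        return (
            g1p * self.basis.dy1(t)
            + g2p * self.basis.dy2(t)
            + g1 * self.basis.ddy1(t)
            + g2 * self.basis.ddy2(t)
        )


def variation_of_parameters_particular(
    basis: HomogeneousBasis,
    g: Callable[[float], float],
    alpha: float,
    t0: float,
    t_end: float,
) -> ParticularSolution:
    """Build the particular solution on [t0, t_end] by adaptive quadrature.

    gamma1' = -y2 g / (a^2 W), gamma2' = y1 g / (a^2 W) are integrated from
    t0 with a high-order adaptive scheme and dense output; the Wronskian is
    monitored and a degenerate basis raises.
    """
    if basis.alpha != alpha:
        raise ValueError("alpha mismatch between basis and request")
    a2 = alpha**2

    def rhs(t, _y):
        W = basis.classical_wronskian(t)
        if abs(W) < _WRONSKIAN_FLOOR:
            raise ArithmeticError(f"classical Wronskian ~ 0 at t={t}; basis degenerate")
        gt = g(t)
        return [-basis.y2(t) * gt / (a2 * W), basis.y1(t) * gt / (a2 * W)]

    sol = integrate.solve_ivp(
        rhs,
        (t0, t_end),
        [0.0, 0.0],
        method="DOP853",
        rtol=1e-11,
        atol=1e-13,
        dense_output=True,
    )
    if not sol.success:
        raise ArithmeticError(f"quadrature for gamma1, gamma2 failed: {sol.message}")
    return ParticularSolution(basis=basis, g=g, t0=t0, _dense=sol.sol)


def solve_mass_spring(
    params: MassSpringParams,
    g: Callable[[float], float],
    y0: float,
    Dy0: float,
    t_grid,
):
    """Full initial-value solution y = c1 y1 + c2 y2 + y_p on ``t_grid``.

    Initial data are the displacement ``y0`` and the *proportional*
    derivative value ``Dy0`` at the first grid time, so that alpha = 1
    reduces to the standard (y, y') problem. Returns displacement samples.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    t0, t_end = float(t_grid[0]), float(t_grid[-1])
    basis = homogeneous_basis(params)
    yp = variation_of_parameters_particular(basis, g, params.alpha, t0, t_end)

    # y_p(t0) = 0 and D^a y_p(t0) = (1-a)*0 + a*0 = 0, so the constants see
    # the raw initial data.
    A = np.array(
        [
            [basis.y1(t0), basis.y2(t0)],
            [basis.prop_d(1, t0), basis.prop_d(2, t0)],
        ]
    )
    if abs(np.linalg.det(A)) < _WRONSKIAN_FLOOR:
        raise ArithmeticError("degenerate basis: singular initial-condition system")
    c1, c2 = np.linalg.solve(A, [y0, Dy0])
    return c1 * basis.y1(t_grid) + c2 * basis.y2(t_grid) + yp(t_grid)
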