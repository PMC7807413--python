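"""Proportional Laplace transform (LT-p) coefficient algebra.

The proportional derivative with linear gains, D^a f = (1-a) f + a f', has a
Laplace transform rule analogous to the classical one:

    L{D^a phi}       = (a s + 1 - a) Phi(s) - a phi(0)
    L{D^{(n)a} phi}  = (a s + 1 - a)^n Phi(s)
                       - sum_k  B_k(s) phi^(k)(0),      k = 0 .. n-1,

where the boundary polynomial multiplying phi^(k)(0) is

    B_k(s) = a^(k+1) * sum_{r=0}^{n-1-k} C(n, r) (a s)^(n-1-k-r) (1-a)^r.

Equivalently the n-fold proportional derivative expands binomially over the
classical derivatives,

    D^{(n)a} phi = sum_{r=0}^{n} C(n, r) a^(n-r) (1-a)^r phi^(n-r),

and the transform rule is the n-fold composition of the first-order rule.
Both routes are implemented (the composition as an internal cross-check) and
agree exactly in rational arithmetic.

Polynomials in the transform variable ``s`` are stored as ascending
coefficient sequences; when ``alpha`` is a :class:`fractions.Fraction` the
whole algebra stays exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from fracvent.local_calculus import DerivativeSpec, Family
from fracvent.phase import PhaseSolution

__all__ = [
    "PropLTRule",
    "OperatorExpansion",
    "lt_nth_order_rule",
    "compose_first_order_rules",
    "expand_nth_prop_derivative",
    "apply_expansion",
    "solve_linear_phase_ltp",
]


def _binom(n: int, r: int):
    return math.comb(n, r)


def _poly_mul(p: Sequence, q: Sequence) -> tuple:
    out = [0 * (p[0] * q[0])] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        for j, b in enumerate(q):
            out[i + j] = out[i + j] + a * b
    return tuple(out)


def _poly_pow(p: Sequence, n: int) -> tuple:
    out: tuple = (p[0] * 0 + 1,)
    for _ in range(n):
        out = _poly_mul(out, p)
    return out


def _poly_add(p: Sequence, q: Sequence) -> tuple:
    n = max(len(p), len(q))
    zero = (list(p) + list(q))[0] * 0
    out = [zero] * n
    for i, a in enumerate(p):
        out[i] = out[i] + a
    for i, b in enumerate(q):
        out[i] = out[i] + b
    return tuple(out)


def _poly_scale(c, p: Sequence) -> tuple:
    return tuple(c * a for a in p)


@dataclass(frozen=True)
class PropLTRule:
    """Transform rule for the n-fold proportional derivative.

    ``L{D^{(n)a} phi} = multiplier(s) Phi(s) - sum_k boundary_coeffs[k](s) phi^(k)(0)``

    Polynomials are ascending coefficient tuples in ``s``; ``multiplier`` has
    degree n and ``boundary_coeffs[k]`` degree n-1-k. Coefficients are exact
    (Fraction) when ``alpha`` is a Fraction.
    """

    n: int
    alpha: object
    multiplier: tuple
    boundary_coeffs: tuple


@dataclass(frozen=True)
class OperatorExpansion:
    """Binomial expansion of the n-fold proportional derivative.

    ``weights[r]`` multiplies the classical derivative ``phi^(n-r)``; weights
    sum to 1 by the binomial theorem on (alpha + (1 - alpha))^n.
    """

    n: int
    alpha: object
    weights: tuple


def lt_nth_order_rule(n: int, alpha) -> PropLTRule:
    """Direct construction of the LT-p rule for the n-fold derivative."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    one = alpha / alpha if alpha else 1  # unit of the coefficient ring
    a, am1 = alpha, one - alpha
    multiplier = _poly_pow((am1, a), n)
    boundary = []
    for k in range(n):
        poly = [a * 0] * (n - k)  # degree n-1-k
        for r in range(n - k):
            # C(n, r) (a s)^(n-1-k-r) (1-a)^r
            deg = n - 1 - k - r
            poly[deg] = poly[deg] + _binom(n, r) * a**deg * am1**r
        boundary.append(_poly_scale(a ** (k + 1), tuple(poly)))
    return PropLTRule(n=n, alpha=alpha, multiplier=multiplier, boundary_coeffs=tuple(boundary))


def compose_first_order_rules(n: int, alpha) -> PropLTRule:
    """n-fold composition of the first-order rule; must equal
    :func:`lt_nth_order_rule` exactly.

    The recursion uses L{D^n phi} = (a s + 1 - a) L{D^(n-1) phi}
    - a (D^(n-1) phi)(0), with (D^(n-1) phi)(0) expanded binomially over the
    classical derivatives at 0.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    one = alpha / alpha if alpha else 1
    a, am1 = alpha, one - alpha
    first = (am1, a)
    multiplier: tuple = first
    boundary: list[tuple] = [(a,)]
    for m in range(2, n + 1):
        exp_prev = expand_nth_prop_derivative(m - 1, alpha)
        multiplier = _poly_mul(first, multiplier)
        new_boundary = [_poly_mul(first, b) for b in boundary] + [(a * 0,)]
        # weight of phi^(k)(0) inside (D^(m-1) phi)(0): weights[m-1-k]
        for k in range(m):
            if k <= m - 1:
                w = exp_prev.weights[m - 1 - k]
                new_boundary[k] = _poly_add(new_boundary[k], (a * w,))
        boundary = new_boundary
    return PropLTRule(n=n, alpha=alpha, multiplier=multiplier, boundary_coeffs=tuple(boundary))


def expand_nth_prop_derivative(n: int, alpha) -> OperatorExpansion:
    """Binomial weights of the n-fold proportional derivative."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    one = alpha / alpha if alpha else 1
    weights = tuple(_binom(n, r) * alpha ** (n - r) * (one - alpha) ** r for r in range(n + 1))
    return OperatorExpansion(n=n, alpha=alpha, weights=weights)


def apply_expansion(expansion: OperatorExpansion, derivs: Sequence) -> object:
    """Apply the expansion to the classical derivatives (phi, phi', ..., phi^(n))
    of a function at a point: returns D^{(n)a} phi there.

    ``derivs[j]`` is the j-th classical derivative; ``weights[r]`` multiplies
    derivs[n - r].
    """
    n = expansion.n
    if len(derivs) != n + 1:
        raise ValueError(f"need {n + 1} derivative values, got {len(derivs)}")
    return sum(w * derivs[n - r] for r, w in enumerate(expansion.weights))


def solve_linear_phase_ltp(
    coefficient_R: float,
    coefficient_invC: float,
    rhs_constant: float,
    anchor: tuple[float, float],
    alpha: float,
) -> PhaseSolution:
    """Solve R D^a V + V / C = rhs (constant) in the transform domain.

    Applying the first-order LT-p rule with V(0) = V0 gives the single-pole
    rational transform

        Phi(s) = (C K + C R a V0 s) / ( s (C R a s + 1 + C R - a C R) ),

    inverted by partial fractions into V(t) = V_inf + (V0 - V_inf) e^{-lam t}
    with V_inf = C K / (1 + CR - a CR) and lam = (1 + CR - a CR) / (a CR).
    Anchors at nonzero times (e.g. the end-of-breath condition V(tb) = 0)
    are handled by time-shift invariance of the constant-coefficient
    equation: the same exponential re-anchored at (t0, V0).

    Parameters are the resistance R, the elastance 1/C, the constant
    right-hand side K (a pressure), the anchor point (t0, V0) and the order.
    Returns a :class:`PhaseSolution` with a proportional-family spec.
    """
    R = float(coefficient_R)
    invC = float(coefficient_invC)
    if R <= 0 or invC <= 0:
        raise ValueError("R and 1/C must be positive")
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    C = 1.0 / invC
    K = float(rhs_constant)
    t0, V0 = float(anchor[0]), float(anchor[1])
    denom = 1.0 + C * R - alpha * C * R
    if denom == 0.0:
        raise ArithmeticError("singular configuration: 1 + CR - alpha CR = 0")

    # Partial-fraction inversion of the zero-anchored transform.
    num = [C * R * alpha * V0, C * K]  # descending in s
    den = [C * R * alpha, denom, 0.0]
    residues, poles, _ = signal.residue(num, den)
    # one pole at s = 0 (the constant) and one at s = -lam (the decay)
    order = np.argsort(np.abs(poles))
    residues, poles = residues[order], poles[order]
    V_inf = float(np.real(residues[0]))
    lam = float(-np.real(poles[1]))

    spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=alpha)
    phase = "inspiration" if K > 0 else "expiration"
    return PhaseSolution(
        spec=spec,
        phase=phase,
        V_inf=V_inf,
        V0=V0,
        t0=t0,
        rate=lam,
        meta={"rhs_constant": K, "R": R, "C": C},
    )
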