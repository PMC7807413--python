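"""Local (limit-based) derivatives of non-integer order and their companions.

Three memoryless derivative families are implemented for smooth scalar
functions, each collapsing to an *equivalence form* when the function is
differentiable:

* proportional (PD-controller type, linear gains kappa1 = 1 - alpha,
  kappa0 = alpha):   D^a f = (1 - a) f + a f'
* conformable:       D^a f = t^(1-a) f'(t),  t > 0
* truncated-M:       D^(a,b) f = t^(1-a) f'(t) / Gamma(b+1),  t > 0

The equivalence forms are the evaluation path everywhere in this package;
the raw epsilon-limit definitions are numerically fragile and survive only
as independent oracles in the test suite.

Also provided: the proportional integral (the inverse of the proportional
derivative), the proportional exponential e_Theta(t, r) (its eigenfunction),
and the truncated Mittag-Leffler partial sum used by the M-derivative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Union

import numpy as np
from scipy import integrate

__all__ = [
    "Family",
    "DerivativeSpec",
    "PropExponentialSpec",
    "eval_local_derivative",
    "prop_exponential",
    "prop_integral",
    "truncated_mittag_leffler",
    "signed_power",
    "numerical_derivative",
]

#: Default quadrature tolerances used by every adaptive integral here.
QUAD_TOL = 1e-10


class Family(str, Enum):
    """Derivative family selector."""

    CLASSICAL = "classical"
    PROPORTIONAL = "proportional"
    CONFORMABLE = "conformable"
    TRUNCATED_M = "truncated_M"


@dataclass(frozen=True)
class DerivativeSpec:
    """Which local derivative to use and its order parameters.

    Parameters
    ----------
    family:
        One of :class:`Family` (strings accepted).
    alpha:
        Order of the derivative. ``0 < alpha <= 1`` for the conformable and
        truncated-M families; the proportional family additionally admits
        ``alpha = 0`` (the identity operator).
    beta:
        Mittag-Leffler parameter, required (``> 0``) for the truncated-M
        family and meaningless otherwise.
    kappa_choice:
        Gain pair for the proportional family. Only ``"linear"`` is shipped:
        ``kappa1 = 1 - alpha``, ``kappa0 = alpha``.
    """

    family: Family = Family.CLASSICAL
    alpha: float = 1.0
    beta: float | None = None
    kappa_choice: str = "linear"

    def __post_init__(self) -> None:
        fam = Family(self.family)
        object.__setattr__(self, "family", fam)
        if fam is Family.PROPORTIONAL:
            if not (0.0 <= self.alpha <= 1.0):
                raise ValueError(f"proportional family needs 0 <= alpha <= 1, got {self.alpha}")
        elif not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"{fam.value} family needs 0 < alpha <= 1, got {self.alpha}")
        if fam is Family.TRUNCATED_M:
            if self.beta is None or self.beta <= 0:
                raise ValueError("truncated_M family requires beta > 0")
        elif self.beta is not None:
            raise ValueError(f"beta is only meaningful for truncated_M, got beta={self.beta}")
        if self.kappa_choice != "linear":
            raise ValueError("only the linear gain pair kappa1=1-alpha, kappa0=alpha is shipped")

    @property
    def gamma_beta(self) -> float:
        """Gamma(beta + 1), the truncated-M scale factor (1.0 for other families)."""
        if self.family is Family.TRUNCATED_M:
            return math.gamma(self.beta + 1.0)
        return 1.0


def signed_power(x, alpha: float):
    """Real branch of x^alpha for any sign of x: sgn(x) * |x|^alpha.

    The unique continuous odd extension of the positive-axis power; it is
    the branch under which the tb-anchored expiration solutions decay and
    recover the classical exponential at alpha = 1.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.abs(x) ** alpha
    return out if out.ndim else float(out)


def numerical_derivative(f: Callable[[float], float], t: float, h: float = 1e-6) -> float:
    """Fourth-order central difference; fallback when no analytic f' is given."""
    return (-f(t + 2 * h) + 8 * f(t + h) - 8 * f(t - h) + f(t - 2 * h)) / (12 * h)


def eval_local_derivative(
    f: Callable[[float], float],
    spec: DerivativeSpec,
    t: float,
    fprime: Callable[[float], float] | None = None,
) -> float:
    """Evaluate the local derivative of ``f`` at ``t`` under ``spec``.

    Uses the differentiable-function equivalence forms. ``fprime`` supplies
    the classical first derivative; when omitted it is approximated by a
    high-order central difference (adequate for smooth test functions, not
    for production residual checks, which pass analytic derivatives).
    """
    fam = spec.family
    if fam in (Family.CONFORMABLE, Family.TRUNCATED_M) and t <= 0:
        raise ValueError(f"{fam.value} derivative requires t > 0, got t={t}")
    df = fprime(t) if fprime is not None else numerical_derivative(f, t)
    if fam is Family.CLASSICAL:
        return df
    if fam is Family.PROPORTIONAL:
        a = spec.alpha
        return (1.0 - a) * f(t) + a * df
    # conformable and truncated-M share the t^(1-alpha) dilation
    val = t ** (1.0 - spec.alpha) * df
    if fam is Family.TRUNCATED_M:
        val /= spec.gamma_beta
    return val


ThetaLike = Union[float, Callable[[float], float]]


@dataclass(frozen=True)
class PropExponentialSpec:
    """The proportional exponential e_Theta(t, r).

    e_Theta(t, r) = exp( -int_r^t (kappa1(a,tau) - Theta(tau)) / kappa0(a,tau) dtau )

    is the eigenfunction of the proportional derivative with eigenvalue
    Theta(t). ``theta`` may be a constant or a function of time; the gains
    default to the linear pair and may be overridden by callables of
    ``(alpha, t)`` (kappa0 must not vanish on the integration interval).
    """

    theta: ThetaLike = 0.0
    r: float = 0.0
    kappa0: Callable[[float, float], float] = field(
        default=lambda alpha, t: alpha, repr=False
    )
    kappa1: Callable[[float, float], float] = field(
        default=lambda alpha, t: 1.0 - alpha, repr=False
    )

    def theta_at(self, t: float) -> float:
        return self.theta(t) if callable(self.theta) else float(self.theta)


def prop_exponential(spec: PropExponentialSpec, alpha: float, t: float) -> float:
    """Evaluate the proportional exponential e_Theta(t, r).

    With the linear gains and constant Theta this is
    exp(-((1 - alpha) - Theta) (t - r) / alpha); in general the exponent is
    obtained by adaptive quadrature.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"prop_exponential needs 0 < alpha <= 1, got {alpha}")
    k0r = spec.kappa0(alpha, spec.r)
    if k0r == 0:
        raise ValueError("kappa0 vanishes at the anchor; e_Theta undefined")

    def integrand(tau: float) -> float:
        k0 = spec.kappa0(alpha, tau)
        if k0 == 0:
            raise ValueError(f"kappa0 vanishes at tau={tau}")
        return (spec.kappa1(alpha, tau) - spec.theta_at(tau)) / k0

    val, _ = integrate.quad(integrand, spec.r, t, epsabs=QUAD_TOL, epsrel=QUAD_TOL)
    return math.exp(-val)


def prop_integral(
    f: Callable[[float], float], alpha: float, a: float, t: float
) -> float:
    """Proportional integral of ``f`` from ``a`` to ``t`` (linear gains).

    I^a f(t) = int_a^t exp(((alpha - 1)/alpha) (t - tau)) f(tau) dtau / alpha.

    The proportional derivative of t -> I^a f(t) recovers f(t); at alpha = 1
    this is the ordinary integral.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"prop_integral needs 0 < alpha <= 1, got {alpha}")
    c = (alpha - 1.0) / alpha

    def integrand(tau: float) -> float:
        return math.exp(c * (t - tau)) * f(tau) / alpha

    val, err = integrate.quad(integrand, a, t, epsabs=QUAD_TOL, epsrel=QUAD_TOL, limit=200)
    if not math.isfinite(val) or err > 1e-6 * max(1.0, abs(val)):
        raise ArithmeticError(
            f"proportional-integral quadrature did not converge: value={val}, err={err}"
        )
    return val


def truncated_mittag_leffler(
    beta: float, z: float, n_terms: int = 40, tol: float = 1e-16
) -> float:
    """Partial sum sum_{k=0}^{n_terms} z^k / Gamma(beta k + 1).

    ``n_terms`` is the truncation index of the one-parameter Mittag-Leffler
    series; summation stops early once a term falls below ``tol`` in
    magnitude.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if n_terms < 0:
        raise ValueError(f"n_terms must be >= 0, got {n_terms}")
    total = 0.0
    for k in range(n_terms + 1):
        term = z**k / math.gamma(beta * k + 1.0)
        total += term
        if k > 0 and abs(term) < tol:
            break
    return total
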