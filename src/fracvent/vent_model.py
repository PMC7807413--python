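"""Single-compartment lung model under pressure-controlled ventilation.

The ventilator applies a constant driving pressure Pd to the airway during
inspiration (0 <= t <= tj) and nothing during expiration (tj <= t <= tb).
The pressure balance at the airway,

    Pl + Pk + Pm = Paw,     Pl = R * (D V),   Pk = V / C,

with D one of the local derivatives (classical, proportional, conformable,
truncated-M), gives one first-order linear equation per phase. All phases
solve in the shared closed form

    V(t) = V_inf + (V0 - V_inf) exp(-rate * (w(t) - w(t0)))

(:class:`~fracvent.phase.PhaseSolution`), with

* proportional:  V_inf = C K / (1 + CR - a CR),
                 rate  = (1 + CR - a CR) / (a CR),   w(t) = t
* conformable:   V_inf = C K, rate = 1/(CR),         w warped, sgn|t-t0|^a / a
* truncated-M:   as conformable with rate Gamma(b+1)/(CR)

where K = Pd - Pm during inspiration and K = -Pm during expiration.

Residual pressure Pm is the constant offset that makes the lung empty by the
end of the breath (Ve(tb) = 0). The classical formula

    Pm = Pd (e^{tj/RC} - 1) / (e^{tb/RC} - 1)

is exact only for the classical dynamics; a self-consistent per-family Pm
that enforces Vi(tj) = Ve(tj) at any order is also provided, and both reduce
to the same value at alpha = 1 (beta = 1).

Units follow clinical convention: pressures in cm H2O, volumes in L,
resistance in cm H2O.s/L, compliance in L/cm H2O, times in s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import integrate

from fracvent.local_calculus import DerivativeSpec, Family
from fracvent.phase import PhaseSolution

__all__ = [
    "VentParams",
    "ResidualPressurePolicy",
    "BreathWaveform",
    "residual_pressure",
    "inspiration_solution",
    "expiration_solution",
    "inspiration_solution_from_tidal",
    "expiration_solution_from_tidal",
    "printed_tidal_inspiration",
    "tidal_volume",
    "mean_alveolar_pressure",
    "mean_alveolar_pressure_closed_form",
    "pressure_decomposition",
    "breath_waveform",
    "max_deviation_from_classical",
    "ConsistencyError",
]


class ConsistencyError(AssertionError):
    """Raised when a computed waveform violates its own pressure balance."""


@dataclass(frozen=True)
class VentParams:
    """Ventilator and lung constants.

    Defaults are the reference setting used for all shipped figures:
    R = 10 cm H2O.s/L, C = 0.02 L/cm H2O, Pd = 20 cm H2O, tj = 1 s, tb = 3 s.
    """

    R: float = 10.0
    C: float = 0.02
    Pd: float = 20.0
    tj: float = 1.0
    tb: float = 3.0

    def __post_init__(self) -> None:
        if self.R <= 0 or self.C <= 0 or self.tj <= 0:
            raise ValueError("R, C and tj must be positive")
        if self.tb <= self.tj:
            raise ValueError(f"tb ({self.tb}) must exceed tj ({self.tj})")
        if self.Pd < 0:
            raise ValueError("Pd must be nonnegative")


@dataclass(frozen=True)
class ResidualPressurePolicy:
    """How the residual pressure Pm is chosen.

    * ``classical_formula``: the alpha-independent classical expression
      (what the reference figures use for every order).
    * ``self_consistent``: the per-family value enforcing Vi(tj) = Ve(tj),
      hence Ve(tb) = 0, at the requested order.
    * ``explicit``: a user-supplied value (cm H2O, >= 0).
    """

    mode: Literal["classical_formula", "self_consistent", "explicit"] = "classical_formula"
    value: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("classical_formula", "self_consistent", "explicit"):
            raise ValueError(f"unknown Pm policy mode {self.mode!r}")
        if self.mode == "explicit":
            if self.value is None or self.value < 0:
                raise ValueError("explicit Pm policy needs a nonnegative value")
        elif self.value is not None:
            raise ValueError("value is only meaningful in explicit mode")


def _prop_rate(params: VentParams, alpha: float) -> float:
    CR = params.C * params.R
    denom = 1.0 + CR - alpha * CR
    if denom <= 0.0:
        raise ArithmeticError("singular configuration: 1 + CR - alpha CR <= 0")
    return denom / (alpha * CR)


def _family_rate(params: VentParams, spec: DerivativeSpec) -> float:
    """Decay rate of the warped-time exponential for each family."""
    if spec.family in (Family.CLASSICAL, Family.PROPORTIONAL):
        alpha = spec.alpha if spec.family is Family.PROPORTIONAL else 1.0
        return _prop_rate(params, alpha)
    return spec.gamma_beta / (params.C * params.R)


def _v_inf(params: VentParams, K: float, spec: DerivativeSpec) -> float:
    if spec.family in (Family.CLASSICAL, Family.PROPORTIONAL):
        alpha = spec.alpha if spec.family is Family.PROPORTIONAL else 1.0
        CR = params.C * params.R
        return params.C * K / (1.0 + CR - alpha * CR)
    return params.C * K


def residual_pressure(
    params: VentParams,
    spec: DerivativeSpec,
    policy: ResidualPressurePolicy = ResidualPressurePolicy(),
) -> float:
    """Residual pressure Pm (cm H2O) under the chosen policy."""
    if policy.mode == "explicit":
        return float(policy.value)
    if policy.mode == "classical_formula":
        RC = params.R * params.C
        return params.Pd * math.expm1(params.tj / RC) / math.expm1(params.tb / RC)
    # self-consistent: enforce Vi(tj) = Ve(tj) for the family at this order
    fam = spec.family
    if fam in (Family.CLASSICAL, Family.PROPORTIONAL):
        alpha = spec.alpha if fam is Family.PROPORTIONAL else 1.0
        lam = _prop_rate(params, alpha)
        return params.Pd * math.expm1(lam * params.tj) / math.expm1(lam * params.tb)
    lam = _family_rate(params, spec)
    a = spec.alpha
    u = lam * params.tj**a / a
    v = lam * (params.tb - params.tj) ** a / a
    return params.Pd * (1.0 - math.exp(-u)) / (math.exp(v) - math.exp(-u))


def inspiration_solution(
    params: VentParams, Pm: float, spec: DerivativeSpec, v0: float = 0.0
) -> PhaseSolution:
    """Inspiration closed form anchored at V(0) = v0 (default: empty lung)."""
    if Pm >= params.Pd:
        warnings.warn(
            f"Pm={Pm} >= Pd={params.Pd}: the lung is not filling", stacklevel=2
        )
    K = params.Pd - Pm
    return PhaseSolution(
        spec=spec,
        phase="inspiration",
        V_inf=_v_inf(params, K, spec),
        V0=v0,
        t0=0.0,
        rate=_family_rate(params, spec),
        meta={"K": K, "Pm": Pm},
    )


def expiration_solution(params: VentParams, Pm: float, spec: DerivativeSpec) -> PhaseSolution:
    """Expiration closed form anchored at the end-of-breath condition V(tb) = 0."""
    K = -Pm
    return PhaseSolution(
        spec=spec,
        phase="expiration",
        V_inf=_v_inf(params, K, spec),
        V0=0.0,
        t0=params.tb,
        rate=_family_rate(params, spec),
        meta={"K": K, "Pm": Pm},
    )


def inspiration_solution_from_tidal(
    params: VentParams, Pm: float, VT: float, spec: DerivativeSpec
) -> PhaseSolution:
    """Inspiration closed form anchored at the phase switch, V(tj) = VT.

    This is the *corrected* form V_inf + (VT - V_inf) e^{-rate (w(t)-w(tj))};
    the historically printed expressions for this anchor miss their own
    boundary condition by 2 V_inf (see :func:`printed_tidal_inspiration`).
    """
    if VT < 0:
        raise ValueError("tidal volume must be nonnegative")
    K = params.Pd - Pm
    return PhaseSolution(
        spec=spec,
        phase="inspiration",
        V_inf=_v_inf(params, K, spec),
        V0=VT,
        t0=params.tj,
        rate=_family_rate(params, spec),
        meta={"K": K, "Pm": Pm, "VT": VT},
    )


def expiration_solution_from_tidal(
    params: VentParams, Pm: float, VT: float, spec: DerivativeSpec
) -> PhaseSolution:
    """Expiration closed form anchored at the phase switch, V(tj) = VT."""
    if VT < 0:
        raise ValueError("tidal volume must be nonnegative")
    K = -Pm
    return PhaseSolution(
        spec=spec,
        phase="expiration",
        V_inf=_v_inf(params, K, spec),
        V0=VT,
        t0=params.tj,
        rate=_family_rate(params, spec),
        meta={"K": K, "Pm": Pm, "VT": VT},
    )


def printed_tidal_inspiration(
    params: VentParams, Pm: float, VT: float, spec: DerivativeSpec
) -> Callable[[float], float]:
    """Verbatim (uncorrected) tidal-anchored inspiration expressions.

    Kept for documentation and erratum tests only: evaluated at t = tj these
    give VT - 2 V_inf (proportional) or VT + 2 V_inf (conformable/M) instead
    of VT, i.e. they violate the anchor they were solved for. Production
    code uses :func:`inspiration_solution_from_tidal`.
    """
    R, C, Pd, tj = params.R, params.C, params.Pd, params.tj
    a = spec.alpha
    if spec.family is Family.PROPORTIONAL:
        CR = C * R
        lam = _prop_rate(params, a)
        neg = -1.0 - CR + a * CR

        def v(t):
            num = (
                a * CR * Pd
                - a * CR * Pm
                - a * R * VT
                - a * C * R**2 * VT
                + a**2 * C * R**2 * VT
            )
            return C * (Pd - Pm) / neg + np.exp(-lam * (t - tj)) * num / (a * R * neg)

        return v
    if spec.family in (Family.CONFORMABLE, Family.TRUNCATED_M):
        rate = _family_rate(params, spec)

        def v(t):
            dw = np.sign(t - tj) * np.abs(t - tj) ** a / a
            return C * (Pd - Pm) + np.exp(-rate * dw) * (C * (Pd - Pm) + VT)

        return v
    raise ValueError("verbatim forms exist only for the fractional families")


def tidal_volume(params: VentParams, Pm: float, spec: DerivativeSpec) -> float:
    """Tidal volume VT = Vi(tj): lung volume at the inspiration/expiration switch."""
    return float(inspiration_solution(params, Pm, spec)(params.tj))


def mean_alveolar_pressure(params: VentParams, Pm: float, spec: DerivativeSpec) -> float:
    """Mean alveolar pressure (cm H2O): time-averaged elastic pressure during
    inspiration plus the residual pressure.

    Pma = (1 / (C tj)) * int_0^tj Vi(t) dt + Pm, by adaptive quadrature of
    the closed-form inspiration trajectory.
    """
    vi = inspiration_solution(params, Pm, spec)
    val, err = integrate.quad(vi, 0.0, params.tj, epsabs=1e-12, epsrel=1e-12, limit=200)
    if not math.isfinite(val):
        raise ArithmeticError("mean-alveolar-pressure quadrature failed")
    return val / (params.C * params.tj) + Pm


def mean_alveolar_pressure_closed_form(
    params: VentParams, Pm: float, spec: DerivativeSpec
) -> float:
    """Antiderivative route for the classical/proportional families (cross-check).

    int_0^tj [V_inf (1 - e^{-lam t})] dt = V_inf tj - (V_inf/lam)(1 - e^{-lam tj}).
    """
    if spec.family not in (Family.CLASSICAL, Family.PROPORTIONAL):
        raise ValueError("closed-form antiderivative implemented for the unwarped families")
    vi = inspiration_solution(params, Pm, spec)
    lam, V_inf = vi.rate, vi.V_inf
    area = V_inf * params.tj - (V_inf / lam) * (1.0 - math.exp(-lam * params.tj))
    return area / (params.C * params.tj) + Pm


# ---------------------------------------------------------------------------
# waveform assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreathWaveform:
    """Sampled breath trajectory with its generating closed forms.

    ``segments`` holds (PhaseSolution, t_start, t_end) triples in absolute
    time, one per phase per breath, so downstream consumers (pressure
    decomposition, residual checks) can evaluate analytic derivatives rather
    than differencing samples.
    """

    times: np.ndarray
    volumes: np.ndarray
    phases: np.ndarray
    segments: tuple
    metadata: dict = field(default_factory=dict, compare=False)

    def to_dataframe(self):
        import pandas as pd

        md = self.metadata
        spec: DerivativeSpec = md["spec"]
        return pd.DataFrame(
            {
                "t_s": self.times,
                "volume_L": self.volumes,
                "phase": self.phases,
                "family": spec.family.value,
                "alpha": spec.alpha,
                "beta": math.nan if spec.beta is None else spec.beta,
                "Pm_cmH2O": md["Pm"],
                "VT_L": md["VT"],
            }
        )


def breath_waveform(
    params: VentParams,
    spec: DerivativeSpec,
    policy: ResidualPressurePolicy = ResidualPressurePolicy(mode="self_consistent"),
    assembly_mode: Literal["anchored_start", "end_anchored"] = "anchored_start",
    n_points: int = 200,
    n_breaths: int = 1,
) -> BreathWaveform:
    """Assemble a sampled breath waveform from the closed-form phases.

    ``anchored_start`` builds inspiration from V(0) = 0 and expiration from
    V(tj) = VT, continuous by construction; the lung returns to zero at tb
    exactly when the Pm policy is self-consistent. ``end_anchored`` pairs
    the start-anchored inspiration with the *end*-anchored expiration
    (V(tb) = 0); under the classical Pm formula at alpha < 1 these disagree
    at tj and the jump is recorded in metadata rather than hidden.

    Multiple breaths repeat the pattern with period tb, each breath starting
    from the previous end volume (an approximation: the closed forms assume
    an empty lung at the breath start).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if n_breaths < 1:
        raise ValueError("n_breaths must be >= 1")
    Pm = residual_pressure(params, spec, policy)
    frac = params.tj / params.tb
    n_insp = max(2, int(round(n_points * frac)))
    n_exp = max(2, n_points - n_insp)

    times, volumes, phases, segments = [], [], [], []
    jumps = []
    v_start = 0.0
    for kb in range(n_breaths):
        off = kb * params.tb
        vi = inspiration_solution(params, Pm, spec, v0=v_start)
        vt = float(vi(params.tj))
        if assembly_mode == "anchored_start":
            ve = expiration_solution_from_tidal(params, Pm, vt, spec)
        elif assembly_mode == "end_anchored":
            ve = expiration_solution(params, Pm, spec)
        else:
            raise ValueError(f"unknown assembly mode {assembly_mode!r}")
        jumps.append(vt - float(ve(params.tj)))

        ti = np.linspace(0.0, params.tj, n_insp)
        te = np.linspace(params.tj, params.tb, n_exp)
        # shifted copies keep the closed forms in local breath time
        vi_off = PhaseSolution(
            spec=spec, phase="inspiration", V_inf=vi.V_inf, V0=vi.V0,
            t0=vi.t0 + off, rate=vi.rate, meta=vi.meta,
        )
        ve_off = PhaseSolution(
            spec=spec, phase="expiration", V_inf=ve.V_inf, V0=ve.V0,
            t0=ve.t0 + off, rate=ve.rate, meta=ve.meta,
        )
        times.append(ti + off)
        volumes.append(vi(ti))
        phases.append(np.full(n_insp, "inspiration"))
        times.append(te + off)
        volumes.append(ve(te))
        phases.append(np.full(n_exp, "expiration"))
        segments.append((vi_off, off, off + params.tj))
        segments.append((ve_off, off + params.tj, off + params.tb))
        v_start = float(ve(params.tb))

    md = {
        "params": params,
        "spec": spec,
        "policy": policy,
        "Pm": Pm,
        "VT": float(segments[0][0](params.tj)),
        "assembly_mode": assembly_mode,
        "jump_at_tj": jumps,
        "n_breaths": n_breaths,
    }
    return BreathWaveform(
        times=np.concatenate(times),
        volumes=np.concatenate(volumes),
        phases=np.concatenate(phases),
        segments=tuple(segments),
        metadata=md,
    )


def pressure_decomposition(
    waveform: BreathWaveform,
    params: VentParams,
    Pm: float,
    spec: DerivativeSpec,
    tol: float = 1e-8,
):
    """Per-sample airway pressure split (Pl, Pk, Paw).

    Pl = R * (family derivative of V), Pk = V / C, and the balance
    Pl + Pk + Pm = Paw (Pd during inspiration, 0 during expiration) is
    asserted at every sample; a violation above ``tol`` raises
    :class:`ConsistencyError` since it can only mean an internal bug.
    """
    Pl = np.empty_like(waveform.times)
    Pk = np.empty_like(waveform.times)
    Paw = np.empty_like(waveform.times)
    for sol, t_lo, t_hi in waveform.segments:
        mask = (waveform.times >= t_lo - 1e-12) & (waveform.times <= t_hi + 1e-12)
        mask &= waveform.phases == sol.phase
        t = waveform.times[mask]
        Pl[mask] = params.R * np.asarray(sol.local_derivative(t))
        Pk[mask] = np.asarray(sol(t)) / params.C
        Paw[mask] = params.Pd if sol.phase == "inspiration" else 0.0
    resid = np.max(np.abs(Pl + Pk + Pm - Paw))
    if resid > tol:
        raise ConsistencyError(
            f"pressure balance violated: max |Pl + Pk + Pm - Paw| = {resid:.3e} cm H2O"
        )
    return Pl, Pk, Paw


def max_deviation_from_classical(
    params: VentParams,
    spec: DerivativeSpec,
    Pm: float,
    n_points: int = 200,
) -> float:
    """Max |Vi_family(t) - Vi_classical(t)| on [0, tj] (figure-ordering metric)."""
    t = np.linspace(0.0, params.tj, n_points)
    vi = inspiration_solution(params, Pm, spec)
    vc = inspiration_solution(params, Pm, DerivativeSpec(family=Family.CLASSICAL))
    return float(np.max(np.abs(vi(t) - vc(t))))
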