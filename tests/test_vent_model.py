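"""The ventilation model: residual pressure, closed-form phase solutions,
tidal volume, mean alveolar pressure, pressure decomposition and waveform
assembly."""

import math

import numpy as np
import pytest

from fracvent import (
    DerivativeSpec,
    ResidualPressurePolicy,
    VentParams,
    breath_waveform,
    expiration_solution,
    expiration_solution_from_tidal,
    inspiration_solution,
    inspiration_solution_from_tidal,
    mean_alveolar_pressure,
    pressure_decomposition,
    residual_pressure,
    tidal_volume,
)
from fracvent.local_calculus import Family
from fracvent.vent_model import (
    max_deviation_from_classical,
    mean_alveolar_pressure_closed_form,
    printed_tidal_inspiration,
)
from tests.conftest import figure_specs

# direct evaluation of the classical residual-pressure formula with the
# reference parameters RC=0.2, tj=1, tb=3, Pd=20
PM_CLASSICAL = 20.0 * math.expm1(5.0) / math.expm1(15.0)  # ~9.019e-4 cm H2O

SELF = ResidualPressurePolicy(mode="self_consistent")


class TestResidualPressure:
    def test_zero_driving_pressure(self):
        p = VentParams(Pd=0.0)
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=0.8)
        assert residual_pressure(p, spec) == 0.0
        assert residual_pressure(p, spec, SELF) == 0.0

    def test_classical_formula_reference_value(self, params):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=0.8)
        pm = residual_pressure(params, spec)
        assert pm == pytest.approx(9.018808247270976e-4, rel=1e-12)

    def test_self_consistent_reduces_to_classical_at_alpha_one(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            R, C = rng.uniform(5, 20), rng.uniform(0.01, 0.05)
            tj = rng.uniform(0.5, 2.0)
            p = VentParams(R=R, C=C, Pd=rng.uniform(5, 30), tj=tj, tb=tj + rng.uniform(1, 3))
            for spec in (
                DerivativeSpec(family=Family.CLASSICAL),
                DerivativeSpec(family=Family.PROPORTIONAL, alpha=1.0),
                DerivativeSpec(family=Family.CONFORMABLE, alpha=1.0),
                DerivativeSpec(family=Family.TRUNCATED_M, alpha=1.0, beta=1.0),
            ):
                assert residual_pressure(p, spec, SELF) == pytest.approx(
                    residual_pressure(p, spec), abs=1e-12
                )

    def test_self_consistent_closes_the_breath(self, params):
        for spec in figure_specs():
            pm = residual_pressure(params, spec, SELF)
            vt_in = inspiration_solution(params, pm, spec)(params.tj)
            vt_ex = expiration_solution(params, pm, spec)(params.tj)
            assert vt_in == pytest.approx(vt_ex, abs=1e-12)

    def test_explicit_policy_passthrough(self, params):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=0.8)
        pol = ResidualPressurePolicy(mode="explicit", value=1.5)
        assert residual_pressure(params, spec, pol) == 1.5
        with pytest.raises(ValueError):
            ResidualPressurePolicy(mode="explicit", value=-1.0)


class TestPhaseSolutions:
    def test_boundary_conditions_all_families(self, params):
        for spec in figure_specs():
            pm = residual_pressure(params, spec)
            assert abs(inspiration_solution(params, pm, spec)(0.0)) < 1e-10
            assert abs(expiration_solution(params, pm, spec)(params.tb)) < 1e-10

    def test_classical_correspondence_at_unit_order(self, params):
        pm = PM_CLASSICAL
        t_in = np.linspace(0.0, params.tj, 100)
        t_ex = np.linspace(params.tj, params.tb, 100)
        want_in = params.C * (params.Pd - pm) * (1 - np.exp(-t_in / (params.C * params.R)))
        want_ex = params.C * pm * (np.exp((params.tb - t_ex) / (params.C * params.R)) - 1)
        for spec in (
            DerivativeSpec(family=Family.PROPORTIONAL, alpha=1.0),
            DerivativeSpec(family=Family.CONFORMABLE, alpha=1.0),
            DerivativeSpec(family=Family.TRUNCATED_M, alpha=1.0, beta=1.0),
        ):
            np.testing.assert_allclose(
                inspiration_solution(params, pm, spec)(t_in), want_in, atol=1e-12
            )
            np.testing.assert_allclose(
                expiration_solution(params, pm, spec)(t_ex), want_ex, atol=1e-12
            )

    def test_proportional_asymptote(self, params):
        # at alpha = 1 the filling lung approaches C (Pd - Pm) ~ 0.39998 L
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=1.0)
        vi = inspiration_solution(params, PM_CLASSICAL, spec)
        assert vi.V_inf == pytest.approx(0.3999819623835055, rel=1e-12)
        t = np.linspace(0.0, params.tj, 50)
        v = vi(t)
        assert np.all(v <= vi.V_inf + 1e-15)
        assert np.all(np.diff(v) > 0)

    def test_inspiration_warns_when_not_filling(self, params):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=0.8)
        with pytest.warns(UserWarning, match="not filling"):
            inspiration_solution(params, params.Pd + 1.0, spec)


class TestTidalAnchoredSolutions:
    @pytest.mark.parametrize(
        "spec",
        [
            DerivativeSpec(family=Family.PROPORTIONAL, alpha=0.8),
            DerivativeSpec(family=Family.CONFORMABLE, alpha=0.8),
            DerivativeSpec(family=Family.TRUNCATED_M, alpha=0.8, beta=0.8),
        ],
        ids=lambda s: s.family.value,
    )
    def test_corrected_forms_anchor_exactly(self, params, spec):
        pm = residual_pressure(params, spec)
        VT = tidal_volume(params, pm, spec)
        assert inspiration_solution_from_tidal(params, pm, VT, spec)(params.tj) == pytest.approx(
            VT, abs=1e-15
        )
        assert expiration_solution_from_tidal(params, pm, VT, spec)(params.tj) == pytest.approx(
            VT, abs=1e-15
        )

    @pytest.mark.parametrize(
        "spec,sign",
        [
            (DerivativeSpec(family=Family.PROPORTIONAL, alpha=0.8), -1),
            (DerivativeSpec(family=Family.CONFORMABLE, alpha=0.8), +1),
            (DerivativeSpec(family=Family.TRUNCATED_M, alpha=0.8, beta=0.8), +1),
        ],
        ids=lambda v: v.family.value if hasattr(v, "family") else str(v),
    )
    def test_printed_forms_miss_their_anchor_by_two_vinf(self, params, spec, sign):
        # the historically printed switch-anchored inspiration forms give
        # VT + sign * 2 V_inf at t = tj instead of VT
        pm = residual_pressure(params, spec)
        VT = tidal_volume(params, pm, spec)
        printed = printed_tidal_inspiration(params, pm, VT, spec)
        v_inf = inspiration_solution(params, pm, spec).V_inf
        assert printed(params.tj) - VT == pytest.approx(sign * 2.0 * v_inf, rel=1e-10)

    def test_expiration_from_tidal_closes_breath_at_alpha_one(self, params):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=1.0)
        pm = residual_pressure(params, spec, SELF)
        VT = tidal_volume(params, pm, spec)
        ve = expiration_solution_from_tidal(params, pm, VT, spec)
        assert abs(ve(params.tb)) < 1e-10

    def test_proportional_form_equals_printed_expiration_expression(self, params):
        # the printed switch-anchored expiration IS algebraically correct;
        # check the simplified solution against a literal transcription
        rng = np.random.default_rng(11)
        C, R, tj = params.C, params.R, params.tj
        for _ in range(50):
            alpha = rng.uniform(0.2, 1.0)
            t = rng.uniform(tj, params.tb)
            spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=alpha)
            pm = residual_pressure(params, spec)
            VT = tidal_volume(params, pm, spec)
            lam = (1 + C * R - alpha * C * R) / (alpha * C * R)
            e = math.exp(-lam * (t - tj))
            printed = (
                e
                * (-C * pm + C * pm / e - VT - C * R * VT + alpha * C * R * VT)
                / (-1 - C * R + alpha * C * R)
            )
            ours = expiration_solution_from_tidal(params, pm, VT, spec)(t)
            assert ours == pytest.approx(printed, abs=1e-12)


class TestScalarOutputs:
    def test_tidal_volume_zero_when_no_pressure_difference(self, params):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=0.8)
        with pytest.warns(UserWarning):
            assert tidal_volume(params, params.Pd, spec) == 0.0

    def test_tidal_volume_reference_value(self, params):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=1.0)
        assert tidal_volume(params, PM_CLASSICAL, spec) == pytest.approx(
            0.39728690512037523, rel=1e-12
        )

    def test_tidal_volume_monotone_in_residual_pressure(self, params):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=0.7)
        vals = [tidal_volume(params, pm, spec) for pm in np.linspace(0.0, 19.0, 12)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_mean_alveolar_pressure_degenerate(self, params):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=0.8)
        with pytest.warns(UserWarning):
            assert mean_alveolar_pressure(params, params.Pd, spec) == pytest.approx(
                params.Pd, abs=1e-12
            )

    def test_mean_alveolar_pressure_reference_value(self, params):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=1.0)
        assert mean_alveolar_pressure(params, PM_CLASSICAL, spec) == pytest.approx(
            16.02713094879625, rel=1e-9
        )

    def test_quadrature_matches_antiderivative(self, params):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=0.8)
        pm = residual_pressure(params, spec)
        assert mean_alveolar_pressure(params, pm, spec) == pytest.approx(
            mean_alveolar_pressure_closed_form(params, pm, spec), abs=1e-9
        )


class TestWaveformAssembly:
    def test_anchored_start_is_continuous_and_closes(self, params):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=0.8)
        wf = breath_waveform(params, spec, policy=SELF, assembly_mode="anchored_start")
        assert wf.volumes[0] == 0.0
        assert abs(wf.volumes[-1]) < 1e-10
        assert abs(wf.metadata["jump_at_tj"][0]) < 1e-12

    def test_modes_agree_at_alpha_one(self, params):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=1.0)
        a = breath_waveform(params, spec, assembly_mode="anchored_start",
                            policy=ResidualPressurePolicy())
        b = breath_waveform(params, spec, assembly_mode="end_anchored",
                            policy=ResidualPressurePolicy())
        np.testing.assert_allclose(a.volumes, b.volumes, atol=1e-10)

    @pytest.mark.parametrize("alpha", [0.25, 0.7, 1.0])
    def test_monotone_filling_then_emptying(self, params, alpha):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=alpha)
        wf = breath_waveform(params, spec, policy=SELF, n_points=120)
        insp = wf.volumes[wf.phases == "inspiration"]
        exp = wf.volumes[wf.phases == "expiration"]
        assert np.all(np.diff(insp) > 0)
        assert np.all(np.diff(exp) < 0)

    def test_multi_breath_repeats_pattern(self, params):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=0.8)
        wf = breath_waveform(params, spec, policy=SELF, n_points=60, n_breaths=3)
        assert wf.times[-1] == pytest.approx(3 * params.tb)
        assert len(wf.segments) == 6
        # self-consistent Pm: every breath starts from an (almost) empty lung
        starts = wf.volumes[np.isin(wf.times, [0.0, params.tb, 2 * params.tb])]
        assert np.all(np.abs(starts) < 1e-9)

    def test_pressure_decomposition_balances(self, params):
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=0.8)
        wf = breath_waveform(params, spec, policy=SELF)
        pm = wf.metadata["Pm"]
        Pl, Pk, Paw = pressure_decomposition(wf, params, pm, spec)
        assert np.max(np.abs(Pl + Pk + pm - Paw)) < 1e-8
        # classical steady state: Pl -> 0, Pk -> Pd - Pm as the lung fills
        spec1 = DerivativeSpec(family=Family.PROPORTIONAL, alpha=1.0)
        vi = inspiration_solution(params, pm, spec1)
        assert vi.local_derivative(50.0) * params.R == pytest.approx(0.0, abs=1e-12)
        assert vi(50.0) / params.C == pytest.approx(params.Pd - pm, abs=1e-12)

    def test_proportional_steady_state_split(self, params):
        # where V = V_inf the proportional derivative of the constant branch
        # leaves Pl = R (1 - alpha) V_inf and Pk = V_inf / C
        alpha = 0.8
        spec = DerivativeSpec(family=Family.PROPORTIONAL, alpha=alpha)
        pm = residual_pressure(params, spec)
        vi = inspiration_solution(params, pm, spec)
        t_far = 40.0  # decay long gone
        assert params.R * vi.local_derivative(t_far) == pytest.approx(
            params.R * (1 - alpha) * vi.V_inf, rel=1e-9
        )
        assert vi(t_far) / params.C == pytest.approx(vi.V_inf / params.C, rel=1e-12)

    def test_family_ordering_near_classical(self, params):
        # at alpha = 0.9, beta = 0.8 the proportional solution hugs the
        # classical curve more closely than conformable or truncated-M
        pm = PM_CLASSICAL
        dev = {
            fam: max_deviation_from_classical(params, spec, pm)
            for fam, spec in [
                ("proportional", DerivativeSpec(family=Family.PROPORTIONAL, alpha=0.9)),
                ("conformable", DerivativeSpec(family=Family.CONFORMABLE, alpha=0.9)),
                ("truncated_M", DerivativeSpec(family=Family.TRUNCATED_M, alpha=0.9, beta=0.8)),
            ]
        }
        assert dev["proportional"] < dev["conformable"]
        assert dev["proportional"] < dev["truncated_M"]
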