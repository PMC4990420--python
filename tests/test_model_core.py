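"""Unit tests for the model right-hand side: gating curves, currents,
calcium fluxes, and structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prebotc.model_core import (
    InvalidParameterError,
    InvalidStateError,
    ModelParameters,
    StateVector,
    calcium_fluxes,
    compute_currents,
    gate_steady_state,
    gate_time_constant,
    make_rhs,
    rhs,
)


def state(V=-50.0, h=0.4, n=0.1, Ca_i=0.1, Ca_tot=2.0, l=0.8):
    return StateVector(V=V, h=h, n=n, Ca_i=Ca_i, Ca_tot=Ca_tot, l=l)


class TestGates:
    def test_sigmoid_midpoint_is_half(self):
        assert gate_steady_state(-40.0, -40.0, -6.0) == pytest.approx(0.5)

    def test_sigmoid_asymptotes(self):
        assert gate_steady_state(-1e4, -40.0, 5.0) == pytest.approx(1.0)
        assert gate_steady_state(1e4, -40.0, 5.0) == pytest.approx(0.0)

    def test_hand_evaluated_sigmoid(self):
        # 1/(1+e^-1) for V=-34, midpoint -40, slope -6
        assert gate_steady_state(-34.0, -40.0, -6.0) == pytest.approx(
            0.7310585786300049, rel=1e-12)

    def test_zero_slope_rejected(self):
        with pytest.raises(InvalidParameterError):
            gate_steady_state(-40.0, -40.0, 0.0)
        with pytest.raises(InvalidParameterError):
            gate_time_constant(-40.0, 10.0, -40.0, 0.0)

    def test_time_constant_peak_and_hand_value(self):
        assert gate_time_constant(-48.0, 10000.0, -48.0, 5.0) == 10000.0
        # 10000/cosh(1) at 10 mV off-midpoint with slope 5
        assert gate_time_constant(-38.0, 10000.0, -48.0, 5.0) == pytest.approx(
            6480.542736638854, rel=1e-12)

    @given(st.floats(-80, 20), st.floats(0.5, 30))
    @settings(max_examples=50, deadline=None)
    def test_time_constant_even_symmetry(self, d, sx):
        vx = -48.0
        left = gate_time_constant(vx - d, 1000.0, vx, sx)
        right = gate_time_constant(vx + d, 1000.0, vx, sx)
        assert left == pytest.approx(right, rel=1e-9)

    @given(st.floats(-90, 30), st.floats(-89.9, 30.1))
    @settings(max_examples=100, deadline=None)
    def test_sigmoid_monotone_and_bounded(self, v1, v2):
        lo, hi = sorted((v1, v2))
        a = gate_steady_state(lo, -40.0, -6.0)
        b = gate_steady_state(hi, -40.0, -6.0)
        assert 0.0 < a < 1.0 and 0.0 < b < 1.0
        assert a <= b  # negative slope = activation curve


class TestCurrents:
    def test_zero_conductance_zeroes_component(self):
        p = ModelParameters(gNaP=0.0)
        assert compute_currents(state(), p).INaP == 0.0

    def test_ican_half_saturation(self):
        p = ModelParameters(gCAN=2.0)
        s = state(Ca_i=p.KCAN, V=-50.0)
        cur = compute_currents(s, p)
        assert cur.ICAN == pytest.approx(0.5 * 2.0 * (-50.0 - p.VNaP))

    def test_full_breakdown_matches_hand_evaluation(self):
        # frozen independent evaluation at V=-50, h=0.4, n=0.1, Ca=0.1
        cur = compute_currents(state(), ModelParameters())
        assert cur.INaP == pytest.approx(-15.886910488091518, rel=1e-10)
        assert cur.INa == pytest.approx(-0.15139759563523264, rel=1e-10)
        assert cur.IK == pytest.approx(0.0168, rel=1e-10)
        assert cur.IL == pytest.approx(27.0, rel=1e-10)
        assert cur.ICa == pytest.approx(-1.5886910488091517, rel=1e-10)
        assert cur.ICAN == pytest.approx(-29.761904761904763, rel=1e-10)
        assert cur.Ih == 0.0
        assert cur.total == pytest.approx(
            sum([cur.INaP, cur.INa, cur.IK, cur.IL, cur.ICa, cur.ICAN,
                 cur.Ih]))

    @pytest.mark.parametrize("g,comp", [
        ("gNaP", "INaP"), ("gNa", "INa"), ("gK", "IK"), ("gL", "IL"),
        ("gCa", "ICa"), ("gCAN", "ICAN"),
    ])
    def test_each_current_linear_in_its_conductance(self, g, comp):
        s = state()
        base = ModelParameters()
        one = getattr(compute_currents(s, base.with_updates(**{g: 1.0})), comp)
        three = getattr(compute_currents(s, base.with_updates(**{g: 3.0})),
                        comp)
        assert three == pytest.approx(3.0 * one, rel=1e-12)

    def test_as_printed_mode_has_ohmic_k_and_no_fast_na(self):
        p = ModelParameters(spiking_mode="as_printed")
        cur = compute_currents(state(), p)
        assert cur.INa == 0.0
        assert cur.IL == 0.0
        assert cur.IK == pytest.approx(p.gK * (-50.0 - p.VK))


class TestFluxes:
    def test_zero_gradient_zero_er_flux(self):
        p = ModelParameters()
        s = state(Ca_i=0.1, Ca_tot=0.1 * (1 + p.sigma))  # Ca_ER == Ca_i
        f = calcium_fluxes(s, p, ICa=0.0)
        assert f.J_ER_in == pytest.approx(0.0, abs=1e-12)

    def test_serca_half_activation(self):
        p = ModelParameters()
        s = state(Ca_i=p.KSERCA, Ca_tot=2.0)
        f = calcium_fluxes(s, p, ICa=0.0)
        assert f.J_ER_out == pytest.approx(p.VSERCA / 2.0)

    def test_zero_ica_zero_pm_influx(self):
        f = calcium_fluxes(state(), ModelParameters(), ICa=0.0)
        assert f.J_PM_in == 0.0

    def test_hand_evaluated_fluxes(self):
        f = calcium_fluxes(state(), ModelParameters(),
                           ICa=-1.5886910488091517)
        assert f.J_ER_in == pytest.approx(165.1855297297298, rel=1e-10)
        assert f.J_ER_out == pytest.approx(80.0, rel=1e-10)
        assert f.J_PM_in == pytest.approx(0.08737800768450334, rel=1e-10)
        assert f.J_PM_out == pytest.approx(0.2, rel=1e-10)

    def test_negative_er_calcium_rejected(self):
        with pytest.raises(InvalidStateError):
            calcium_fluxes(state(Ca_i=1.0, Ca_tot=0.5),
                           ModelParameters(), ICa=0.0)


class TestRhs:
    def test_gate_fixed_points(self):
        p = ModelParameters()
        V = -55.0
        hinf = gate_steady_state(V, p.vh, p.sh)
        Ca = 0.1
        linf = p.Kd / (Ca + p.Kd)
        s = state(V=V, h=hinf, Ca_i=Ca, l=linf)
        d = rhs(0.0, s, p)
        assert d.h == pytest.approx(0.0, abs=1e-14)
        assert d.l == pytest.approx(0.0, abs=1e-14)

    def test_closed_membrane_conserves_total_calcium(self):
        p = ModelParameters(alpha=0.0, VPMCA=0.0)
        d = rhs(0.0, state(), p)
        assert d.Ca_tot == 0.0

    def test_all_zero_conductances_reduce_to_iapp_over_cm(self):
        p = ModelParameters(gNaP=0, gNa=0, gK=0, gL=0, gCAN=0, gCa=0, gh=0)
        d = rhs(0.0, state(), p, I_app=21.0)
        assert d.V == pytest.approx(21.0 / p.Cm)

    def test_non_finite_state_rejected(self):
        with pytest.raises(InvalidStateError):
            rhs(0.0, state(V=float("nan")), ModelParameters())

    def test_fast_path_matches_structured_path(self, rng):
        """The array RHS integrated by the solver must agree with the
        readable dataclass implementation everywhere."""
        p = ModelParameters()
        f = make_rhs(p, I_app=3.0)
        for _ in range(25):
            s = state(V=rng.uniform(-90, 10), h=rng.uniform(0, 1),
                      n=rng.uniform(0, 1), Ca_i=rng.uniform(0.01, 1.5),
                      Ca_tot=rng.uniform(1.6, 3.0), l=rng.uniform(0, 1))
            want = rhs(0.0, s, p, I_app=3.0)
            got = f(0.0, s.as_array())
            assert np.allclose(got, list(want), rtol=1e-12)


class TestParameters:
    def test_defaults_reproduce_published_constants(self):
        p = ModelParameters()
        assert (p.Cm, p.gNa, p.gK, p.gL, p.gCa) == (21.0, 28.0, 11.2, 2.7,
                                                    0.05)
        assert (p.VNaP, p.VNa, p.VK, p.VL, p.VCa) == (50.0, 50.0, -65.0,
                                                      -60.0, 150.0)
        assert (p.vm, p.sm, p.vh, p.sh) == (-40.0, -6.0, -48.0, 5.0)
        assert (p.tau_h_bar, p.tau_n_bar, p.KCAN) == (10000.0, 10.0, 0.74)
        assert (p.lam, p.fi, p.Vi, p.sigma) == (0.03, 1e-4, 4.0, 0.185)
        assert (p.IP3, p.A, p.Kd, p.KI, p.Ka) == (1.0, 5e-4, 0.4, 1.0, 0.4)
        assert (p.LIP3R, p.PIP3R) == (0.37, 31000.0)
        assert (p.VSERCA, p.KSERCA) == (400.0, 0.2)
        assert (p.alpha, p.VPMCA, p.KPMCA) == (0.055, 2.0, 0.3)
        assert p.gh == 0.0

    @pytest.mark.parametrize("bad", [
        dict(Cm=0.0), dict(gNaP=-1.0), dict(fi=0.0), dict(fi=1.5),
        dict(sigma=0.0), dict(KCAN=0.0), dict(tau_n_bar=0.0),
        dict(sh=0.0), dict(spiking_mode="bogus"),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            ModelParameters(**bad)

    def test_dict_round_trip_and_unknown_key(self):
        p = ModelParameters(gCAN=1.25)
        q = ModelParameters.from_dict(p.to_dict())
        assert q == p
        with pytest.raises(InvalidParameterError):
            ModelParameters.from_dict({"gXYZ": 1.0})

    def test_state_validation(self):
        with pytest.raises(InvalidStateError):
            state(h=1.5).validate()
        with pytest.raises(InvalidStateError):
            state(Ca_i=-0.1).validate()
        state().validate()
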