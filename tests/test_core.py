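"""Unit and property tests for the two-compartment neuron core."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from lcnet.core import (IntegrationError, ahp_gate, ca_drive_factor,
                        calcium_steady_state, calcium_update,
                        dendrite_derivative, gating_steady_state,
                        resting_state, soma_derivative, step)
from lcnet.params import (CA_DRIVE_PEAK_MV, NeuronParams, NeuronState,
                          ParameterError, StimulusProtocol)

P = NeuronParams()


class TestAhpGate:
    @pytest.mark.parametrize("ca, expected", [
        (0.0, 0.0),
        (1.0, 0.5),                 # half-saturation
        (1.3, 1.3 / 2.3),           # 0.5652...
    ])
    def test_values(self, ca, expected):
        assert ahp_gate(ca) == pytest.approx(expected, abs=1e-12)

    def test_negative_calcium_rejected(self):
        with pytest.raises(ParameterError):
            ahp_gate(-0.1)

    def test_bounded(self):
        ca = np.logspace(-3, 3, 50)
        r = ahp_gate(ca)
        assert np.all((r >= 0) & (r <= 1))


class TestCalciumDrive:
    def test_midpoint(self):
        # logistic equals 1/2 at v = -25, so the drive is (120+25)/2
        assert ca_drive_factor(-25.0, 120.0) == pytest.approx(72.5)

    def test_hyperpolarized_limit(self):
        assert ca_drive_factor(-200.0, 120.0) == pytest.approx(0.0, abs=1e-20)

    def test_peak_is_132_6(self):
        res = minimize_scalar(lambda v: -ca_drive_factor(v),
                              bounds=(-60.0, 120.0), method="bounded")
        assert -res.fun == pytest.approx(CA_DRIVE_PEAK_MV, abs=0.1)

    def test_steady_state_peak_equals_m_ca(self):
        # the printed normalization (132.6) is rounded to 0.1 mV, so the
        # maximum matches M_Ca to the same 0.1% the params validation uses
        v = np.linspace(-80.0, 120.0, 20001)
        assert calcium_steady_state(v, P).max() == \
            pytest.approx(P.m_ca, rel=1e-3)

    def test_steady_state_at_minus_25(self):
        assert calcium_steady_state(-25.0, P) == \
            pytest.approx(42.4 * 72.5 / 132.6, rel=1e-6)

    def test_m_ca_consistency_enforced(self):
        # f_ca*k_ca*tau_ca*132.6 must match m_ca to 0.1%
        implied = P.f_ca * P.k_ca * P.tau_ca * CA_DRIVE_PEAK_MV
        assert implied == pytest.approx(P.m_ca, rel=1e-3)
        with pytest.raises(ParameterError):
            NeuronParams(f_ca=0.004)


class TestCalciumUpdate:
    def test_fixed_point(self):
        v = -30.0
        s = calcium_steady_state(v, P)
        assert calcium_update(s, v, 5.0, P) == pytest.approx(s, rel=1e-12)

    def test_one_tau_from_zero(self):
        v = -20.0
        s = calcium_steady_state(v, P)
        got = calcium_update(0.0, v, P.tau_ca, P)
        assert got == pytest.approx(s * (1.0 - math.exp(-1.0)), rel=1e-12)

    def test_exact_composition(self):
        # the update solves the frozen-voltage linear ODE exactly, so two
        # half steps equal one full step to machine precision
        v, ca, dt = -10.0, 3.7, 13.0
        one = calcium_update(ca, v, dt, P)
        two = calcium_update(calcium_update(ca, v, dt / 2, P), v, dt / 2, P)
        assert two == pytest.approx(one, rel=1e-14)

    def test_rejects_bad_dt(self):
        with pytest.raises(ParameterError):
            calcium_update(0.1, -60.0, 0.0, P)


class TestDerivatives:
    def test_no_conductances_no_input_is_zero(self):
        p0 = NeuronParams(g_na=0, g_k=0, g_p=0, g_ahp=0, g_ca=0, g_l=0,
                          g_ld=0, g_c=0)
        s = NeuronState(v_s=-55.0, v_d=-55.0, ca=0.0)
        assert soma_derivative(s, p0) == 0.0

    def test_leak_at_reversal_is_zero(self):
        p0 = NeuronParams(g_na=0, g_k=0, g_p=0, g_ahp=0, g_ca=0, g_c=0)
        s = NeuronState(v_s=p0.v_l, v_d=p0.v_l, ca=0.0)
        assert soma_derivative(s, p0) == pytest.approx(0.0, abs=1e-12)

    def test_dendrite_equilibrium_is_zero(self):
        s = NeuronState(v_s=P.v_ld, v_d=P.v_ld)
        assert dendrite_derivative(s, P) == pytest.approx(0.0, abs=1e-12)

    def test_negative_girk_conductance_rejected(self):
        with pytest.raises(ParameterError):
            soma_derivative(NeuronState(), P, g_girk_total=-0.1)

    def test_nonfinite_state_raises(self):
        with pytest.raises(IntegrationError):
            soma_derivative(NeuronState(v_s=float("nan")), P)


class TestStep:
    def test_quiescent_neuron_only_clock_advances(self):
        p0 = NeuronParams(g_na=0, g_k=0, g_p=0, g_ahp=0, g_ca=0, g_l=0,
                          g_ld=0, g_c=0)
        v0 = -48.0
        m, h, n = gating_steady_state(v0, p0)
        ca0 = calcium_steady_state(v0, p0)
        s = NeuronState(v_s=v0, v_d=v0, m=m, h=h, n=n, ca=ca0)
        s2 = step(s, p0, dt=0.025)
        assert s2.t == pytest.approx(0.025)
        assert s2.v_s == pytest.approx(v0, abs=1e-12)
        assert s2.m == pytest.approx(m, rel=1e-12)
        assert s2.ca == pytest.approx(ca0, rel=1e-12)

    def test_gating_and_ahp_bounded_along_trajectory(self):
        s = resting_state(P)
        for _ in range(4000):   # 100 ms spanning a spike
            s = step(s, P, dt=0.025, i_elec=30.0)
            for g in (s.m, s.h, s.n, s.ahp_gate()):
                assert 0.0 <= g <= 1.0
            assert s.ca >= 0.0

    def test_blowup_raises_with_timestamp(self):
        s = resting_state(P)
        with pytest.raises(IntegrationError, match="ms"):
            for _ in range(300):
                s = step(s, P, dt=5.0, i_elec=300.0)

    def test_dt_halving_convergence_first_order(self):
        # subthreshold 40 ms segment: global error should scale ~ dt
        def v_at_end(dt):
            s = resting_state(P)
            for _ in range(int(40.0 / dt)):
                s = step(s, P, dt=dt, i_elec=1.0)
            return s.v_s

        ref = v_at_end(0.003125)
        e1 = abs(v_at_end(0.05) - ref)
        e2 = abs(v_at_end(0.025) - ref)
        assert e2 < e1
        assert e1 / e2 == pytest.approx(2.0, rel=0.5)


class TestEngineAgreement:
    def test_python_step_matches_engine(self, step_amp):
        """The reference step() and the compiled engine integrate alike."""
        from lcnet.network import simulate_neuron
        proto = StimulusProtocol(steps=((5.0, 40.0, step_amp),))
        res = simulate_neuron(protocol=proto, duration_ms=60.0,
                              dt_ms=0.025, noise=False, seed=0)
        s = resting_state(P)
        for i in range(int(60.0 / 0.025)):
            t = i * 0.025
            s = step(s, P, dt=0.025, i_elec=proto.current(t))
        assert s.v_s == pytest.approx(res.v_s[0][-1], abs=2.0)


class TestSpontaneousRate:
    def test_deterministic_without_noise(self):
        from lcnet.network import simulate_neuron
        a = simulate_neuron(duration_ms=5000.0, noise=False, seed=1)
        b = simulate_neuron(duration_ms=5000.0, noise=False, seed=2)
        np.testing.assert_array_equal(a.spikes[0], b.spikes[0])

    def test_same_seed_bit_identical(self):
        from lcnet.network import simulate_neuron
        a = simulate_neuron(duration_ms=3000.0, seed=7)
        b = simulate_neuron(duration_ms=3000.0, seed=7)
        np.testing.assert_array_equal(a.spikes[0], b.spikes[0])
        np.testing.assert_array_equal(a.v_s, b.v_s)

    def test_rate_near_4_3_hz(self, spont_results):
        rates = [r.rate(0) for r in spont_results]
        assert np.mean(rates) == pytest.approx(4.3, abs=0.25)
        assert np.std(rates, ddof=1) <= 0.1
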