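"""Two-compartment conductance-based LC neuron: membrane and calcium dynamics.

The somatic compartment carries Hodgkin-Huxley sodium and delayed-rectifier
potassium currents, a persistent sodium current, a calcium-gated AHP
potassium current, leak, the GIRK current and the coupling current to the
passive dendritic compartment:

    c_m dV_S/dt = I_elec - I_Na - I_K - I_P - I_AHP - I_Ca - I_GIRK
                  - I_dend - I_L + eta(t)
    c_m dV_D/dt = -I_soma - I_GJ - I_LD

Cytosolic calcium relaxes exponentially (tau_Ca = 80 ms) toward a
voltage-dependent steady state whose maximum is M_Ca = 42.4 uM; the AHP
gate is the instantaneous saturation r = [Ca]/([Ca] + 1 uM).
"""

from __future__ import annotations

import math

import numpy as np

from .params import (CA_DRIVE_PEAK_MV, NeuronParams, NeuronState,
                     ParameterError, StimulusProtocol)

__all__ = [
    "IntegrationError",
    "ahp_gate",
    "ca_drive_factor",
    "calcium_steady_state",
    "calcium_update",
    "rate_constants",
    "gating_steady_state",
    "soma_derivative",
    "dendrite_derivative",
    "step",
]


class IntegrationError(RuntimeError):
    """Numerical blow-up during integration (suggests a smaller dt)."""


# ---------------------------------------------------------------------------
# calcium subsystem

def ahp_gate(ca, k_half: float = 1.0):
    """AHP gate r = [Ca]/([Ca] + k_half); r is in [0, 1].

    Parameters
    ----------
    ca : float or array
        Cytosolic calcium in uM; must be non-negative.
    k_half : float
        Half-saturation (1 uM).
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ParameterError("calcium must be >= 0")
    out = ca / (ca + k_half)
    return float(out) if out.ndim == 0 else out


def ca_drive_factor(v, v_ca: float = 120.0):
    """Voltage-dependent drive (v_ca - v) / (1 + exp(-(v + 25)/2.5)) in mV.

    For v_ca = 120 mV this peaks at 132.6 mV (near v = -15 mV), the
    constant that normalizes the calcium steady state.
    """
    v = np.asarray(v, dtype=float)
    out = (v_ca - v) / (1.0 + np.exp(-(v + 25.0) / 2.5))
    return float(out) if out.ndim == 0 else out


def calcium_steady_state(v, params: NeuronParams):
    """[Ca]_inf(v) = (M_Ca / 132.6 mV) * drive(v); maximum equals M_Ca (uM)."""
    return params.m_ca / CA_DRIVE_PEAK_MV * ca_drive_factor(v, params.v_ca)


def calcium_update(ca, v, dt: float, params: NeuronParams):
    """Exact exponential relaxation of calcium over one step of dt ms.

    [Ca]_{i+1} = [Ca]_inf + ([Ca]_i - [Ca]_inf) exp(-dt/tau_Ca) with the
    steady state evaluated at the current voltage.  Being the exact
    solution of the frozen-voltage linear ODE, two half steps compose to
    one full step to machine precision.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    cinf = calcium_steady_state(v, params)
    out = cinf + (np.asarray(ca, dtype=float) - cinf) * \
        math.exp(-dt / params.tau_ca)
    # concentration cannot go negative (the steady state changes sign
    # above V_Ca, outside the model's physiological voltage range)
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# Hodgkin-Huxley kinetics

def rate_constants(v: float, params: NeuronParams):
    """Forward/backward rates (1/ms) of m, h, n at voltage v (mV).

    Classic squid-type rate functions referenced to a -60 mV resting
    potential; the delayed-rectifier rates are evaluated at
    v - k_shift, displacing its activation depolarized so the resting
    potassium conductance stays small (pacemaker requirement).
    """
    vt = v + 60.0
    am = 0.1 * (25.0 - vt) / (math.exp((25.0 - vt) / 10.0) - 1.0) \
        if abs(25.0 - vt) > 1e-9 else 1.0
    bm = 4.0 * math.exp(-vt / 18.0)
    ah = 0.07 * math.exp(-vt / 20.0)
    bh = 1.0 / (math.exp((30.0 - vt) / 10.0) + 1.0)
    vn = vt - params.k_shift
    an = 0.01 * (10.0 - vn) / (math.exp((10.0 - vn) / 10.0) - 1.0) \
        if abs(10.0 - vn) > 1e-9 else 0.1
    bn = 0.125 * math.exp(-vn / 80.0)
    return am, bm, ah, bh, an, bn


def gating_steady_state(v: float, params: NeuronParams):
    am, bm, ah, bh, an, bn = rate_constants(v, params)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def _p_inf(v: float, params: NeuronParams) -> float:
    return 1.0 / (1.0 + math.exp(-(v - params.p_half) / params.p_slope))


# ---------------------------------------------------------------------------
# membrane equations

def membrane_currents(state: NeuronState, params: NeuronParams,
                      g_girk_total: float = 0.0,
                      v_girk: float | None = None) -> dict:
    """All somatic current densities (uA/cm^2) at the present state.

    ``g_girk_total`` is the rectified GIRK conductance in mS/cm^2
    (i.e. after unit conversion and synaptic weighting).
    """
    p = params
    v = state.v_s
    r = ahp_gate(state.ca, p.ahp_k_half)
    if v_girk is None:
        v_girk = p.v_k
    return {
        "i_na": p.g_na * state.m ** 3 * state.h * (v - p.v_na),
        "i_k": p.g_k * state.n ** 4 * (v - p.v_k),
        "i_p": p.g_p * _p_inf(v, p) * (v - p.v_na),
        "i_ahp": p.g_ahp * r * (v - p.v_k),
        "i_ca": p.g_ca * (v - p.v_ca),
        "i_girk": g_girk_total * (v - v_girk),
        "i_dend": p.g_c * (state.v_s - state.v_d),
        "i_l": p.g_l * (v - p.v_l),
    }


def soma_derivative(state: NeuronState, params: NeuronParams,
                    i_elec: float = 0.0, g_girk_total: float = 0.0,
                    noise: float = 0.0, v_girk: float | None = None) -> float:
    """dV_S/dt in mV/ms from the somatic current balance.

    Raises :class:`IntegrationError` if the state is non-finite and
    :class:`ParameterError` for a negative GIRK conductance.
    """
    if g_girk_total < 0:
        raise ParameterError("g_girk_total must be >= 0")
    if not math.isfinite(state.v_s) or not math.isfinite(state.ca):
        raise IntegrationError(
            f"non-finite state at t = {state.t:.3f} ms; use a smaller dt")
    cur = membrane_currents(state, params, g_girk_total, v_girk)
    total = (i_elec - cur["i_na"] - cur["i_k"] - cur["i_p"] - cur["i_ahp"]
             - cur["i_ca"] - cur["i_girk"] - cur["i_dend"] - cur["i_l"]
             + noise)
    return total / params.c_m


def dendrite_derivative(state: NeuronState, params: NeuronParams,
                        i_gj: float = 0.0) -> float:
    """dV_D/dt in mV/ms: soma coupling, gap junctions and dendritic leak."""
    if not math.isfinite(state.v_d):
        raise IntegrationError(
            f"non-finite dendritic voltage at t = {state.t:.3f} ms")
    i_soma = params.g_c * (state.v_d - state.v_s)
    i_ld = params.g_ld * (state.v_d - params.v_ld)
    return -(i_soma + i_gj + i_ld) / params.c_m


def step(state: NeuronState, params: NeuronParams, dt: float,
         i_elec: float = 0.0, g_girk_total: float = 0.0,
         noise: float = 0.0, i_gj: float = 0.0) -> NeuronState:
    """Advance one neuron by one time step of dt ms.

    Voltages use an explicit Euler update; gating variables and calcium
    use the exponential (exact frozen-coefficient) update.  Returns a new
    :class:`NeuronState`; raises :class:`IntegrationError` on numerical
    blow-up.
    """
    try:
        dv_s = soma_derivative(state, params, i_elec, g_girk_total, noise)
        dv_d = dendrite_derivative(state, params, i_gj)
        v = state.v_s
        am, bm, ah, bh, an, bn = rate_constants(v, params)
        new = NeuronState(
            v_s=v + dt * dv_s,
            v_d=state.v_d + dt * dv_d,
            m=_exp_gate(state.m, am, bm, dt),
            h=_exp_gate(state.h, ah, bh, dt),
            n=_exp_gate(state.n, an, bn, dt),
            ca=float(calcium_update(state.ca, v, dt, params)),
            t=state.t + dt,
        )
    except OverflowError as exc:
        raise IntegrationError(
            f"integration blew up at t = {state.t:.3f} ms; "
            "use a smaller dt") from exc
    if not (math.isfinite(new.v_s) and math.isfinite(new.v_d)):
        raise IntegrationError(
            f"integration blew up at t = {new.t:.3f} ms; use a smaller dt")
    return new


def _exp_gate(x: float, a: float, b: float, dt: float) -> float:
    tau = 1.0 / (a + b)
    xinf = a * tau
    return xinf + (x - xinf) * math.exp(-dt / tau)


def resting_state(params: NeuronParams, v0: float = -60.0) -> NeuronState:
    """State with gating at steady state for v0 and near-zero calcium."""
    m, h, n = gating_steady_state(v0, params)
    return NeuronState(v_s=v0, v_d=v0, m=m, h=h, n=n, ca=0.05, t=0.0)
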