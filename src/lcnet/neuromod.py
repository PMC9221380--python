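"""Calcium-dependent NE release and the alpha2/GIRK synaptic conductance.

Release of norepinephrine from dense-core vesicles is gated by the
presynaptic cytosolic calcium at the time of each action potential,
through the saturating fraction

    R_rel([Ca]) = 2 [Ca]^k / (Ca_high^k + [Ca]^k),     Ca_high = 1.3 uM,

which equals 1 at the calcium level reached during 20 Hz firing and
saturates at 2 (the form is implemented exactly as printed; no
renormalization).  Each action potential contributes a peak-normalized
double-exponential open-probability transient (tau_fast = 300 ms,
tau_slow = 350 ms) weighted by its release fraction; the summed drive is
multiplied by the voltage-dependent rectification G_rect and the synaptic
strength matrix S_ij to give the GIRK conductance and current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import GIRKParams, ParameterError, ReleaseParams

__all__ = [
    "ReleaseEvent",
    "release_fraction",
    "girk_open_prob",
    "girk_rectification",
    "girk_conductance",
    "girk_current",
    "girk_drive_envelope",
    "girk_decay_tau",
]


@dataclass(frozen=True)
class ReleaseEvent:
    """One NE release, stamped with the presynaptic AP time and calcium."""

    neuron: int
    t_ap: float      # ms
    ca_ap: float     # uM, presynaptic calcium at the AP time

    def __post_init__(self):
        if self.ca_ap < 0:
            raise ParameterError("ca_ap must be >= 0")


def release_fraction(ca_ap, params: ReleaseParams = ReleaseParams()):
    """Release fraction R_rel(ca) = 2 ca^k / (Ca_high^k + ca^k).

    Equals 0 at ca = 0, 1 at ca = Ca_high and saturates at 2.  If the
    optional hard threshold is set, calcium below it releases nothing.
    """
    ca = np.asarray(ca_ap, dtype=float)
    if np.any(ca < 0):
        raise ParameterError("calcium must be >= 0")
    k = params.k_rel
    out = 2.0 * ca ** k / (params.ca_high ** k + ca ** k)
    if params.hard_threshold is not None:
        out = np.where(ca < params.hard_threshold, 0.0, out)
    return float(out) if out.ndim == 0 else out


def girk_open_prob(t, t_ap, params: GIRKParams = GIRKParams()):
    """Peak-normalized open-probability kernel B [f_slow(t) - f_fast(t)].

    Zero for t < t_ap; rises to exactly 1 at t_ap + t_peak where
    t_peak = tau_f tau_s / (tau_s - tau_f) * ln(tau_s / tau_f).
    """
    s = np.asarray(t, dtype=float) - t_ap
    out = params.norm * (np.exp(-s / params.tau_slow)
                         - np.exp(-s / params.tau_fast))
    out = np.where(s < 0.0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def girk_rectification(v, params: GIRKParams = GIRKParams()):
    """Inward-rectification conductance scale in uS/mm^2.

    G_rect(V) = 0.2 / (1 + exp(0.05 (V - V_GIRK))): half the maximal
    0.2 uS/mm^2 at the GIRK reversal, saturating when hyperpolarized.
    """
    v = np.asarray(v, dtype=float)
    out = params.rect_scale / (
        1.0 + np.exp(params.rect_slope * (v - params.v_girk)))
    return float(out) if out.ndim == 0 else out


def _event_sum(t: float, events, gparams: GIRKParams,
               rparams: ReleaseParams) -> float:
    prev = -math.inf
    acc = 0.0
    for ev in events:
        if ev.t_ap < prev:
            raise ParameterError("release events must be sorted by time")
        prev = ev.t_ap
        if t - ev.t_ap > gparams.horizon:
            continue
        acc += girk_open_prob(t, ev.t_ap, gparams) * \
            release_fraction(ev.ca_ap, rparams)
    return acc


def girk_conductance(v_post: float, t: float, events,
                     gparams: GIRKParams = GIRKParams(),
                     rparams: ReleaseParams = ReleaseParams()) -> float:
    """Single-source GIRK conductance (uS/mm^2) from a sorted event list.

    G_rect(v_post) * sum_AP P_open(t - t_AP) R_rel([Ca_AP]); linear in the
    events, non-negative, and zero before the first event.  Events older
    than the configured horizon (10 tau_slow) are dropped.
    """
    return girk_rectification(v_post, gparams) * \
        _event_sum(t, events, gparams, rparams)


def girk_current(v_post: float, t: float, events_by_source: dict,
                 s_row: dict | None = None,
                 gparams: GIRKParams = GIRKParams(),
                 rparams: ReleaseParams = ReleaseParams()) -> float:
    """GIRK current density (uA/cm^2) onto one postsynaptic soma.

    I_GIRK = (V - V_GIRK) * 0.1 * gain * G_rect(V) * sum_j S_ij * drive_j,
    where drive_j is the event sum of source j and the factor 0.1 converts
    uS/mm^2 to mS/cm^2.  Hyperpolarizing (positive, outward) for
    V > V_GIRK.  ``s_row`` maps source id -> S_ij (missing ids contribute
    nothing; default weight 1 for listed sources).
    """
    total = 0.0
    for j, events in events_by_source.items():
        s = 1.0 if s_row is None else float(s_row.get(j, 0.0))
        if s < 0:
            raise ParameterError("synaptic strengths must be >= 0")
        if s == 0.0:
            continue
        total += s * _event_sum(t, events, gparams, rparams)
    g_eff = 0.1 * gparams.gain * girk_rectification(v_post, gparams) * total
    return g_eff * (v_post - gparams.v_girk)


def girk_drive_envelope(t_grid, event_times, weights,
                        gparams: GIRKParams = GIRKParams()):
    """Unrectified kernel-sum drive sum_i w_i P_open(t - t_i) on a grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    out = np.zeros_like(t_grid)
    for ti, w in zip(event_times, weights):
        out += w * girk_open_prob(t_grid, ti, gparams)
    return out


def girk_decay_tau(event_times, weights,
                   gparams: GIRKParams = GIRKParams(),
                   window: tuple = (3000.0, 6000.0),
                   dt: float = 5.0) -> float:
    """Limiting decay time constant (ms) of the summed GIRK drive.

    Fits a single exponential (log-linear least squares) to the kernel-sum
    envelope in a window measured from the last contributing event.  The
    two kernel time constants are close (300/350 ms), so their mixture
    only reaches its limiting tau_slow decay after the separation time
    tau_f tau_s/(tau_s - tau_f) = 2.1 s; the default window starts beyond
    it.  Raises if the envelope underflows in the window.
    """
    if len(event_times) == 0:
        raise ParameterError("need at least one release event")
    t_last = max(event_times)
    t_grid = np.arange(t_last + window[0], t_last + window[1] + dt, dt)
    env = girk_drive_envelope(t_grid, event_times, weights, gparams)
    if np.any(env <= 0):
        raise ParameterError("drive envelope vanished inside the fit window")
    slope = np.polyfit(t_grid, np.log(env), 1)[0]
    return -1.0 / slope
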