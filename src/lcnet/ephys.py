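"""Spike-train and action-potential waveform feature extraction.

Operates on uniformly sampled voltage traces (simulated or two-column
experimental exports).  Spike detection is an upward threshold crossing
with a refractory lockout; waveform features use a dV/dt threshold
criterion for AP onset, peak, half-width and the AHP minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterError

__all__ = [
    "SpikeFeatures",
    "detect_spikes",
    "ap_waveform_features",
    "train_features",
]


@dataclass
class SpikeFeatures:
    """Waveform features of one action potential (mV / ms)."""

    threshold_mv: float
    peak_mv: float
    half_width_ms: float
    ahp_min_mv: float
    ahp_depth_mv: float     # baseline minus AHP minimum; > 0 for a real AHP


def _check_uniform(t_ms: np.ndarray) -> float:
    dt = np.diff(t_ms)
    if dt.size == 0 or np.any(dt <= 0) or \
            not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ParameterError("trace requires a uniform, increasing time base")
    return float(dt[0])


def detect_spikes(t_ms, v_mv, threshold_mv: float = 0.0,
                  refractory_ms: float = 2.0) -> np.ndarray:
    """Spike times (ms) from upward threshold crossings with lockout.

    Returns strictly increasing times; an empty array for a flat trace.
    """
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(v_mv, dtype=float)
    _check_uniform(t)
    up = np.nonzero((v[:-1] < threshold_mv) & (v[1:] >= threshold_mv))[0]
    times = []
    last = -np.inf
    for i in up:
        ti = t[i]
        if ti - last > refractory_ms:
            times.append(ti)
            last = ti
    return np.asarray(times)


def ap_waveform_features(t_ms, v_mv, spike_time: float,
                         context_ms: float = 50.0,
                         dvdt_thresh: float = 20.0,
                         ahp_window_ms: float = 100.0) -> SpikeFeatures:
    """Extract threshold, peak, half-width and AHP depth of one AP.

    The AP onset (threshold) is the last point before the peak where
    dV/dt first exceeds ``dvdt_thresh`` mV/ms; half-width is measured at
    half the threshold-to-peak height; the AHP minimum is searched within
    ``ahp_window_ms`` after the peak.  Raises if the trace does not cover
    ``context_ms`` on both sides of the spike.
    """
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(v_mv, dtype=float)
    dt = _check_uniform(t)
    if spike_time - t[0] < context_ms or t[-1] - spike_time < context_ms:
        raise ParameterError(
            f"need {context_ms} ms of context around the spike")

    i_spk = int(np.searchsorted(t, spike_time))
    w = int(round(context_ms / dt))
    lo, hi = i_spk - w, i_spk + w
    seg_v = v[lo:hi]
    i_peak = lo + int(np.argmax(seg_v))
    peak = float(v[i_peak])

    dvdt = np.gradient(v, dt)
    # walk back from the apex into the rising phase, then to the last
    # point where dV/dt is still below the onset criterion
    i = i_peak
    while i > lo and dvdt[i] < dvdt_thresh:
        i -= 1
    while i > lo and dvdt[i] >= dvdt_thresh:
        i -= 1
    i_thr = i
    thr = float(v[i_thr])

    half = thr + 0.5 * (peak - thr)
    # walk out from the peak to the half-height crossings (interpolated)
    i1 = i_peak
    while i1 > lo and v[i1] > half:
        i1 -= 1
    i2 = i_peak
    while i2 < hi - 1 and v[i2] > half:
        i2 += 1
    t1 = np.interp(half, [v[i1], v[i1 + 1]], [t[i1], t[i1 + 1]]) \
        if v[i1 + 1] != v[i1] else t[i1]
    t2 = np.interp(half, [v[i2], v[i2 - 1]], [t[i2], t[i2 - 1]]) \
        if v[i2 - 1] != v[i2] else t[i2]
    width = float(abs(t2 - t1))

    i_ahp_end = min(v.size, i_peak + int(round(ahp_window_ms / dt)))
    ahp_min = float(v[i_peak:i_ahp_end].min())
    baseline = float(np.median(v[lo:i_thr])) if i_thr > lo else thr
    return SpikeFeatures(threshold_mv=thr, peak_mv=peak,
                         half_width_ms=width, ahp_min_mv=ahp_min,
                         ahp_depth_mv=baseline - ahp_min)


def train_features(spike_times_ms, t0: float = 0.0,
                   t1: float | None = None) -> dict:
    """Rate and ISI statistics of a spike train within [t0, t1)."""
    s = np.asarray(spike_times_ms, dtype=float)
    if t1 is None:
        t1 = s[-1] if s.size else t0
    sel = s[(s >= t0) & (s < t1)]
    isi = np.diff(sel)
    out = {
        "n_spikes": int(sel.size),
        "rate_hz": sel.size / ((t1 - t0) / 1000.0) if t1 > t0 else 0.0,
        "isi_mean_ms": float(isi.mean()) if isi.size else np.nan,
        "isi_median_ms": float(np.median(isi)) if isi.size else np.nan,
        "isi_cv": float(isi.std() / isi.mean()) if isi.size > 1 else np.nan,
    }
    if isi.size >= 3:
        out["early_rate_hz"] = 1000.0 / isi[0]
        out["late_rate_hz"] = 1000.0 / isi[-1]
    return out
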