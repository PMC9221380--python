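"""Extracellular norepinephrine volume transmission.

A quantal release is treated as an instantaneous point source whose
concentration follows the 3-D Green's function of diffusion with optional
first-order reuptake,

    C(r, t) = alpha * exp(-r^2 / (4 D t) - k_up t) / (4 pi D t)^{3/2},

with D = 3.4e-6 cm^2/s.  The source amplitude alpha is calibrated so that
the bolus centre concentration equals the quantal 200 nM at the reference
time t0 = a^2/(4D) at which the Gaussian has spread to the effective
source radius a (default 4 um); equivalently C(r, t) =
C0 (t0/t)^{3/2} exp(-r^2/(4 D t) - k_up t).

Bound alpha2-receptor fraction x(t) follows the first-order kinetics
    tau(C) dx/dt = -x + x_eq(C),   x_eq = C k_on / (C k_on + k_off),
    tau = 1 / (C k_on + k_off),
with k_on = 1 /nM/s and k_off = 1.25 /s (K_D = 1.25 nM), evaluated along
the local concentration trajectory.

The slow, attenuated GIRK drive a release event produces on a neighbour
at distance r is obtained by passing the occupancy trajectory through a
50 ms alpha-function filter (transmitter binding/unbinding kinetics) and
the unit-area G-protein/GIRK machinery kernel, then summarized by a
double-exponential fit (`fit_effective_kernel`) whose amplitude relative
to the synaptic kernel is the attenuation factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .params import DiffusionParams, GIRKParams, ParameterError

__all__ = [
    "ne_concentration",
    "attenuation_profile",
    "receptor_binding",
    "alpha_filter",
    "effective_girk_drive",
    "fit_effective_kernel",
    "ConcentrationField",
    "BindingState",
    "KernelFit",
]


@dataclass
class ConcentrationField:
    """Normalized concentration ratio C/C0 on an (r, t) grid."""

    r_um: np.ndarray
    t_ms: np.ndarray
    ratio: np.ndarray          # shape (len(r), len(t))
    normalization: str = "center-bolus"

    def to_frame(self):
        import pandas as pd
        rr, tt = np.meshgrid(self.r_um, self.t_ms, indexing="ij")
        return pd.DataFrame({
            "r_um": rr.ravel(), "t_ms": tt.ravel(),
            "c_over_c0": self.ratio.ravel(),
        })


@dataclass
class BindingState:
    """Bound alpha2-receptor fraction along a concentration trajectory."""

    t_ms: np.ndarray
    conc_nm: np.ndarray
    x: np.ndarray

    @property
    def peak(self) -> float:
        return float(self.x.max())


@dataclass
class KernelFit:
    """Double-exponential fit of a conductance drive."""

    attenuation: float
    tau_fast: float
    tau_slow: float
    residual: float           # RMS residual / peak
    t_peak: float = field(init=False)

    def __post_init__(self):
        tf, ts = self.tau_fast, self.tau_slow
        self.t_peak = tf * ts / (ts - tf) * math.log(ts / tf)

    def __call__(self, t):
        return _dexp(np.asarray(t, dtype=float), self.attenuation,
                     self.tau_fast, self.tau_slow - self.tau_fast)


def ne_concentration(r_um, t_ms, params: DiffusionParams = DiffusionParams()):
    """Point-source NE concentration in nM at distance r (um), time t (ms).

    t must be > 0 (the Green's function is singular at the origin of
    time).  With k_up = 0 the spatial integral of the un-normalized field
    is conserved; with k_up > 0 total mass decays as exp(-k_up t).
    """
    t = np.asarray(t_ms, dtype=float)
    r = np.asarray(r_um, dtype=float)
    if np.any(t <= 0):
        raise ParameterError("t_ms must be > 0")
    if np.any(r < 0):
        raise ParameterError("r_um must be >= 0")
    p = params
    out = p.c0_nm * (p.t0_ms / t) ** 1.5 * \
        np.exp(-r * r / (4.0 * p.d_um2_ms * t) - p.k_up * t)
    return float(out) if out.ndim == 0 else out


def attenuation_profile(r_grid, t_grid,
                        params: DiffusionParams = DiffusionParams()
                        ) -> ConcentrationField:
    """C(r, t)/C0 relative to the quantal concentration on a grid."""
    r = np.asarray(r_grid, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(r) <= 0) or np.any(np.diff(t) <= 0):
        raise ParameterError("grids must be strictly increasing")
    ratio = ne_concentration(r[:, None], t[None, :], params) / params.c0_nm
    return ConcentrationField(r_um=r, t_ms=t, ratio=ratio)


def receptor_binding(conc_nm, dt_ms: float,
                     params: DiffusionParams = DiffusionParams(),
                     x0: float = 0.0) -> BindingState:
    """Integrate alpha2 binding kinetics along a concentration trajectory.

    Uses the exact exponential update of the locally-linear relaxation
    within each step (concentration frozen per sample), so a constant
    concentration reproduces the closed-form relaxation to
    x_eq = C k_on / (C k_on + k_off) exactly.
    """
    c = np.asarray(conc_nm, dtype=float)
    if np.any(c < 0):
        raise ParameterError("concentrations must be >= 0")
    if dt_ms <= 0:
        raise ParameterError("dt_ms must be > 0")
    x = np.empty_like(c)
    xi = float(x0)
    kon, koff = params.k_on, params.k_off
    for i in range(c.size):
        rate = kon * c[i] + koff
        xeq = kon * c[i] / rate
        xi = xeq + (xi - xeq) * math.exp(-dt_ms * rate)
        x[i] = xi
    t = np.arange(1, c.size + 1) * dt_ms
    return BindingState(t_ms=t, conc_nm=c, x=x)


def alpha_filter(signal, dt_ms: float, tau_ms: float = 50.0):
    """Causal low-pass with the alpha function g(t) = (t/tau) exp(-t/tau).

    The discrete kernel is normalized to unit gain (a constant input is
    returned unchanged); the impulse response peaks at t = tau.
    """
    if dt_ms <= 0 or tau_ms <= 0:
        raise ParameterError("dt_ms and tau_ms must be > 0")
    sig = np.asarray(signal, dtype=float)
    tk = np.arange(0.0, 12.0 * tau_ms, dt_ms)
    g = (tk / tau_ms) * np.exp(-tk / tau_ms)
    g /= g.sum()
    return np.convolve(sig, g)[: sig.size]


def _machinery_kernel(dt_ms: float, gparams: GIRKParams):
    """Unit-area impulse response of the G-protein/GIRK gating cascade."""
    tk = np.arange(0.0, gparams.horizon, dt_ms)
    h = gparams.norm * (np.exp(-tk / gparams.tau_slow)
                        - np.exp(-tk / gparams.tau_fast))
    return h / h.sum()


def effective_girk_drive(distance_um: float,
                         params: DiffusionParams = DiffusionParams(),
                         gparams: GIRKParams = GIRKParams(),
                         dt_ms: float = 2.0, t_max_ms: float = 14000.0):
    """GIRK drive on a neighbour at the given distance from one release.

    Chain: point-source concentration -> receptor occupancy -> 50 ms
    alpha filter -> unit-area GIRK machinery kernel.  Returns (t, drive)
    where drive is on the same scale as the peak-1 synaptic kernel, so
    its maximum is directly the attenuation of volume relative to
    synaptic transmission.
    """
    if distance_um <= 0:
        raise ParameterError("distance_um must be > 0")
    t = np.arange(dt_ms, t_max_ms, dt_ms)
    c = ne_concentration(distance_um, t, params)
    x = receptor_binding(c, dt_ms, params).x
    xf = alpha_filter(x, dt_ms, params.tau_filter)
    drive = np.convolve(xf, _machinery_kernel(dt_ms, gparams))[: t.size]
    return t, drive


def _dexp(t, a, tau_f, dtau):
    tau_s = tau_f + dtau
    tp = tau_f * tau_s / dtau * np.log(tau_s / tau_f)
    b = 1.0 / (np.exp(-tp / tau_s) - np.exp(-tp / tau_f))
    return a * b * (np.exp(-t / tau_s) - np.exp(-t / tau_f))


def fit_effective_kernel(t_ms, drive, p0=None) -> KernelFit:
    """Least-squares double-exponential fit of a conductance drive.

    The fitted family is A * B' [exp(-t/tau_slow) - exp(-t/tau_fast)]
    with B' normalizing the peak to 1, so A is the amplitude relative to
    the synaptic kernel.  Degenerate tau_slow -> tau_fast is handled by
    fitting the gap tau_slow - tau_fast (bounded below at 0.1 ms).
    Raises ParameterError with residual diagnostics if the fit fails.
    """
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(drive, dtype=float)
    peak = y.max()
    if peak <= 0:
        raise ParameterError("drive is non-positive; nothing to fit")
    if p0 is None:
        p0 = (peak, max(t[np.argmax(y)] * 0.7, 10.0), 100.0)
    try:
        popt, _ = curve_fit(_dexp, t, y, p0=p0,
                            bounds=([0.0, 0.1, 0.1], [np.inf, 1e5, 1e5]),
                            maxfev=40000)
    except RuntimeError as exc:  # pragma: no cover - scipy convergence
        raise ParameterError(f"kernel fit did not converge: {exc}") from exc
    resid = float(np.sqrt(np.mean((y - _dexp(t, *popt)) ** 2)) / peak)
    if resid > 0.2:
        raise ParameterError(
            f"kernel fit residual too large (RMS/peak = {resid:.3f})")
    return KernelFit(attenuation=float(popt[0]), tau_fast=float(popt[1]),
                     tau_slow=float(popt[1] + popt[2]), residual=resid)
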