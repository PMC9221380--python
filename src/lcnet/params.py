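"""Parameter containers for the locus coeruleus network model.

All electrical quantities use a uniform density unit system:
voltage in mV, time in ms, conductance density in mS/cm^2, current
density in uA/cm^2, capacitance density in uF/cm^2, calcium in uM,
extracellular norepinephrine in nM, distances in um.

The GIRK rectification scale of Eq-level 0.2 uS/mm^2 is kept in its
native unit and converted to mS/cm^2 (factor 0.1) where it enters the
somatic current balance.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "CA_DRIVE_PEAK_MV",
    "REUPTAKE_LITERATURE_PER_MS",
    "NeuronParams",
    "NeuronState",
    "StimulusProtocol",
    "ReleaseParams",
    "GIRKParams",
    "DiffusionParams",
    "ParameterError",
]

#: Maximum over voltage of the calcium drive factor (V_Ca - V)/(1+exp(-(V+25)/2.5))
#: for V_Ca = 120 mV.  Normalizes the calcium steady state so that its maximum
#: equals M_Ca.
CA_DRIVE_PEAK_MV = 132.6

#: First-order NET reuptake rate of 20 s^-1 quoted for catecholamine volume
#: transmission, in 1/ms.  Not the default (see DiffusionParams.k_up).
REUPTAKE_LITERATURE_PER_MS = 0.02


class ParameterError(ValueError):
    """Raised when a parameter set violates its domain constraints."""


def _replace(obj, **kw):
    return dataclasses.replace(obj, **kw)


@dataclass(frozen=True)
class NeuronParams:
    """Electrical, calcium and release-relevant constants of one LC neuron.

    The spike-generating core is Hodgkin-Huxley-type sodium/potassium
    kinetics with a persistent sodium current; the slow pacemaker rhythm
    is produced by the calcium-gated AHP potassium conductance.  Default
    conductances are calibrated so that the isolated neuron fires
    spontaneously at ~4.3 Hz and accumulates ~1.3 uM cytosolic calcium
    when driven at 20 Hz (see docs/methods.md).
    """

    c_m: float = 1.0              # uF/cm^2
    area_cm2: float = 1.5e-5      # somatic membrane area (sphere of r ~ 11 um)
    g_na: float = 120.0           # mS/cm^2, transient sodium
    g_k: float = 36.0             # mS/cm^2, delayed rectifier
    g_p: float = 0.05             # mS/cm^2, persistent sodium
    g_ahp: float = 2.8            # mS/cm^2, calcium-gated potassium (AHP)
    g_ca: float = 0.0             # mS/cm^2, electrical shadow of I_Ca (off)
    g_l: float = 0.15             # mS/cm^2, somatic leak
    g_ld: float = 0.05            # mS/cm^2, dendritic leak
    g_c: float = 0.15             # mS/cm^2, soma-dendrite coupling
    g_gj: float = 0.0             # mS/cm^2, gap junction to other dendrites
    v_na: float = 55.0            # mV
    v_k: float = -85.0            # mV
    v_ca: float = 120.0           # mV
    v_l: float = -40.0            # mV, somatic leak reversal (pacemaker drive)
    v_ld: float = -60.0           # mV, dendritic leak reversal
    noise_sigma: float = 1.0      # uA/cm^2 sqrt(ms), white-noise current scale
    # Delayed-rectifier activation is shifted depolarized relative to the
    # sodium kinetics so the resting potassium conductance does not pin the
    # membrane below threshold (required for leak-driven pacemaking).
    k_shift: float = 10.0         # mV
    p_half: float = -50.0         # mV, persistent-Na half-activation
    p_slope: float = 4.0          # mV
    # calcium dynamics
    f_ca: float = 0.002           # uM/(mV ms)
    k_ca: float = 2.0             # unitless
    tau_ca: float = 80.0          # ms
    m_ca: float = 42.4            # uM, peak of the calcium steady state
    ahp_k_half: float = 1.0       # uM, AHP gate half-saturation

    def __post_init__(self):
        for name in ("g_na", "g_k", "g_p", "g_ahp", "g_ca", "g_l", "g_ld",
                     "g_c", "g_gj"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.tau_ca <= 0:
            raise ParameterError("tau_ca must be > 0")
        if self.c_m <= 0:
            raise ParameterError("c_m must be > 0")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        # Internal consistency between the f_ca*k_ca*tau_ca formulation of the
        # calcium steady state and its M_Ca normalization.
        implied = self.f_ca * self.k_ca * self.tau_ca * CA_DRIVE_PEAK_MV
        if abs(implied - self.m_ca) > 1e-3 * self.m_ca:
            raise ParameterError(
                "inconsistent calcium parameters: f_ca*k_ca*tau_ca*"
                f"{CA_DRIVE_PEAK_MV} = {implied:.4g} uM but m_ca = "
                f"{self.m_ca:.4g} uM (must agree to 0.1%)")

    replace = _replace


@dataclass
class NeuronState:
    """Evolving state of one two-compartment neuron."""

    v_s: float = -60.0     # mV, somatic voltage
    v_d: float = -60.0     # mV, dendritic voltage
    m: float = 0.05        # Na activation
    h: float = 0.6         # Na inactivation
    n: float = 0.1         # K activation
    ca: float = 0.05       # uM, cytosolic calcium
    t: float = 0.0         # ms

    def validate(self):
        for g in (self.m, self.h, self.n):
            if not (0.0 <= g <= 1.0):
                raise ParameterError("gating variables must lie in [0, 1]")
        if self.ca < 0:
            raise ParameterError("calcium must be >= 0")
        if not all(math.isfinite(x) for x in
                   (self.v_s, self.v_d, self.m, self.h, self.n, self.ca)):
            raise ParameterError("non-finite state")

    def ahp_gate(self, k_half: float = 1.0) -> float:
        return self.ca / (self.ca + k_half)

    def as_array(self):
        import numpy as np
        return np.array([self.v_s, self.v_d, self.m, self.h, self.n, self.ca])


@dataclass(frozen=True)
class StimulusProtocol:
    """Electrode current protocol: list of (onset_ms, duration_ms, amplitude).

    Amplitudes are current densities in uA/cm^2.  Steps must not overlap.
    """

    steps: tuple = ()

    def __post_init__(self):
        steps = tuple(tuple(map(float, s)) for s in self.steps)
        object.__setattr__(self, "steps", steps)
        prev_end = -math.inf
        for onset, dur, _amp in sorted(steps):
            if dur <= 0:
                raise ParameterError("step durations must be > 0")
            if onset < prev_end:
                raise ParameterError("stimulus steps must not overlap")
            prev_end = onset + dur

    def current(self, t: float) -> float:
        for onset, dur, amp in self.steps:
            if onset <= t < onset + dur:
                return amp
        return 0.0

    def to_array(self, dt: float, n_steps: int):
        import numpy as np
        out = np.zeros(n_steps)
        for onset, dur, amp in self.steps:
            i0 = max(0, int(round(onset / dt)))
            i1 = min(n_steps, int(round((onset + dur) / dt)))
            out[i0:i1] = amp
        return out

    @property
    def end(self) -> float:
        return max((o + d for o, d, _ in self.steps), default=0.0)


@dataclass(frozen=True)
class ReleaseParams:
    """Calcium-dependent dense-core-vesicle release of norepinephrine.

    ``release_fraction`` saturates at 2 by construction (the printed form);
    it equals 1 at ca_high, the calcium level reached at 20 Hz firing.
    """

    ca_high: float = 1.3       # uM
    k_rel: float = 1.0         # Hill exponent
    c0_nm: float = 200.0       # nM, quantal extracellular NE concentration
    #: optional hard calcium threshold below which no vesicle is released;
    #: None reproduces the default graded release.
    hard_threshold: float | None = None

    def __post_init__(self):
        if self.ca_high <= 0 or self.c0_nm <= 0:
            raise ParameterError("ca_high and c0_nm must be > 0")
        if self.k_rel < 1:
            raise ParameterError("k_rel must be >= 1")

    replace = _replace


@dataclass(frozen=True)
class GIRKParams:
    """Alpha2 -> G-protein -> GIRK synaptic conductance kernel.

    The open-probability kernel is a peak-normalized double exponential
    with tau_fast = 300 ms, tau_slow = 350 ms; rectification follows a
    Boltzmann of the postsynaptic voltage with scale 0.2 uS/mm^2.  ``gain``
    is the dimensionless synaptic weight that maps the rectified kernel
    conductance onto the somatic current balance; its default is
    calibrated against the somatic-autoinhibition behaviour: after a
    1 s, ~20 Hz activity bout the spontaneous pacemaker stays quiescent
    for several hundred ms, while the driven rate during the bout stays
    within 10% of a GIRK-free control (see docs/methods.md).
    """

    tau_fast: float = 300.0        # ms
    tau_slow: float = 350.0        # ms
    rect_scale: float = 0.2        # uS/mm^2
    rect_slope: float = 0.05       # 1/mV
    v_girk: float = -85.0          # mV (potassium reversal of the neuron)
    gain: float = 3.75             # dimensionless synaptic weight
    horizon_factor: float = 10.0   # drop events older than factor*tau_slow

    def __post_init__(self):
        if not (self.tau_slow > self.tau_fast > 0):
            raise ParameterError("need tau_slow > tau_fast > 0")
        if self.rect_scale <= 0:
            raise ParameterError("rect_scale must be > 0")
        if self.gain < 0:
            raise ParameterError("gain must be >= 0")

    @property
    def t_peak(self) -> float:
        """Time of the kernel maximum after an action potential (ms)."""
        tf, ts = self.tau_fast, self.tau_slow
        return tf * ts / (ts - tf) * math.log(ts / tf)

    @property
    def norm(self) -> float:
        """Normalization B making the kernel peak equal 1."""
        tp = self.t_peak
        return 1.0 / (math.exp(-tp / self.tau_slow) - math.exp(-tp / self.tau_fast))

    @property
    def horizon(self) -> float:
        return self.horizon_factor * self.tau_slow

    replace = _replace


@dataclass(frozen=True)
class DiffusionParams:
    """Extracellular NE point-source diffusion and alpha2 binding kinetics.

    Notes
    -----
    ``k_up`` defaults to zero.  A first-order reuptake of 20 s^-1 is the
    literature value for catecholamine clearance, but norepinephrine
    transporter activity in the LC core is argued to be non-limiting, and
    the far-field behaviour this model is built around (attenuation to
    ~1e-3 of the quantal concentration at 20-25 um over hundreds of ms,
    with >15% receptor occupancy inside that radius) only exists when
    clearance does not dominate; see docs/methods.md.  Set
    ``k_up = REUPTAKE_LITERATURE_PER_MS`` to include it.

    The source amplitude is calibrated through ``source_radius_um``: the
    released quantum is treated as a Gaussian bolus whose centre
    concentration equals the quantal ``c0_nm`` at the moment its RMS
    radius reaches the source radius (t0 = a^2 / 4D).
    """

    d_um2_ms: float = 0.34            # diffusion constant (3.4e-6 cm^2/s)
    k_up: float = 0.0                 # 1/ms, first-order reuptake
    c0_nm: float = 200.0              # nM, quantal concentration
    source_radius_um: float = 4.0     # um, effective source (calibration)
    k_on: float = 1.0e-3              # 1/(nM ms)  (= 1.0 /nM/s)
    k_off: float = 1.25e-3            # 1/ms       (= 1.25 /s, K_D = 1.25 nM)
    tau_filter: float = 50.0          # ms, alpha-function low-pass

    def __post_init__(self):
        for name in ("d_um2_ms", "c0_nm", "source_radius_um", "k_on",
                     "k_off", "tau_filter"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.k_up < 0:
            raise ParameterError("k_up must be >= 0")

    @property
    def t0_ms(self) -> float:
        """Reference time at which the bolus centre equals c0_nm."""
        return self.source_radius_um ** 2 / (4.0 * self.d_um2_ms)

    @property
    def kd_nm(self) -> float:
        return self.k_off / self.k_on

    replace = _replace
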