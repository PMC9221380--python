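# Methods

This note documents the model equations as implemented, the calibration
decisions behind the shipped defaults, the numerical choices, and what
the synthetic data do and do not establish.

## 1. The two-compartment LC neuron

### Membrane equations

Somatic and dendritic voltage follow the current balances given in the
README. All quantities use a uniform density system (mV, ms, μM,
mS/cm², μA/cm², μF/cm²); c_m = 1 μF/cm².

The spike-generating currents are Hodgkin–Huxley-type:

* `I_Na = g_Na m³ h (V − V_Na)` with classic squid-type rate functions
  referenced to a −60 mV rest; g_Na = 120 mS/cm², V_Na = 55 mV.
* `I_K = g_K n⁴ (V − V_K)` with the same rate family evaluated at
  V − 10 mV (`k_shift`); g_K = 36 mS/cm², V_K = −85 mV.
* `I_P = g_P p∞(V)(V − V_Na)`, p∞ a Boltzmann with half-activation
  −50 mV and slope 4 mV; g_P = 0.05 mS/cm².
* `I_AHP = g_AHP r (V − V_K)` with r = [Ca]/([Ca] + 1 μM);
  g_AHP = 2.8 mS/cm².
* `I_L = g_L (V − V_L)` with g_L = 0.15 mS/cm², V_L = −40 mV.
* Dendrite: soma coupling g_c = 0.15 mS/cm², leak g_LD = 0.05 mS/cm²
  to V_LD = −60 mV, resistive gap junctions between dendrites
  (off by default).
* `I_Ca` enters the voltage balance through a configurable conductance
  `g_ca` defaulting to 0: calcium's effect is carried entirely by the
  concentration dynamics below, and the voltage-side contribution of the
  underlying current is far smaller than I_Na/I_K during a spike.

The exact sodium/potassium rate functions of the LC pacemaker are not
constrained by the data this model is built against; they are inherited
kinetics, and two deliberate modifications make the cell a pacemaker
rather than a silent resonator:

1. **Rectifier shift (+10 mV).** With V_K at −85 mV, the resting n⁴
   conductance of the unshifted rates pins the membrane near −63 mV.
   Shifting the rectifier's activation depolarized restores a small
   resting K conductance, letting the leak drive the cell to threshold.
2. **Depolarized leak (V_L = −40 mV).** The leak is the pacemaker drive;
   the calcium-gated AHP opposes it after each spike and its decay
   (through τ_Ca) sets the interspike interval.

g_L, g_AHP and g_P were tuned once, jointly, to the validation surface:
spontaneous rate ≈ 4.3 Hz, calcium plateau ≈ 1.3 μM at 20 Hz, an
approximately linear frequency–current relation, and a broad AP with a
long AHP. They are ordinary parameters in `NeuronParams`, not hard-coded.

### Calcium

Cytosolic calcium relaxes exponentially with τ_Ca = 80 ms toward

    [Ca]∞(V) = (M_Ca / 132.6 mV) · (V_Ca − V) / (1 + exp(−(V + 25)/2.5)),

V_Ca = 120 mV, M_Ca = 42.4 μM. The positive-drive orientation
(V_Ca − V) is used: only with it does the drive factor peak at 132.6 mV
(near V ≈ −15 mV) and the steady state attain M_Ca, and only then is the
equivalent formulation M_Ca = f_Ca·k_Ca·τ_Ca·132.6 mV consistent
(f_Ca = 0.002 μM/(mV·ms), k_Ca = 2). Parameter validation enforces this
identity to 0.1%. The update
`[Ca]ᵢ₊₁ = [Ca]∞ + ([Ca]ᵢ − [Ca]∞)·exp(−dt/τ_Ca)` is the exact solution
of the frozen-voltage linear ODE, so step-halving composes exactly; the
result is clamped at 0 because the steady state changes sign above V_Ca,
outside the physiological range.

At the spontaneous 4.3 Hz the calcium seen at spike times is ≈ 0.05 μM
(release fraction ≈ 0.07); at 20 Hz the plateau is ≈ 1.23 μM and the
spike-time calcium ≈ 0.9–1 μM (release fraction ≈ 0.85–1). High-rate
episodes therefore release strongly while tonic firing releases little —
the mechanism that makes all three inhibition scenarios activity-gated.

### Noise

η(t) is zero-mean white noise, amplitude `noise_sigma = 1 μA/cm²·√ms`,
pre-generated per neuron from the run seed. It was set so that the
spontaneous-rate spread across seeds stays small (SD ≈ 0.01–0.03 Hz over
60 s runs) while still decorrelating spike phases between neurons.

## 2. Release and the GIRK conductance

Each detected action potential (upward 0 mV crossing, 2 ms lockout)
emits a release event weighted by `R_rel([Ca]) = 2[Ca]ᵏ/(Ca_highᵏ+[Ca]ᵏ)`
with k = 1 and Ca_high = 1.3 μM — the form saturates at 2 and equals 1
at the 20 Hz calcium level, and is implemented exactly as stated without
renormalization. Release is graded; an optional hard calcium threshold
exists but is off by default, since the low release fraction at resting
calcium already implements the "only high activity releases" behaviour.

The conductance kernel is the peak-normalized double exponential
`B [exp(−t/τ_slow) − exp(−t/τ_fast)]` (τ = 300/350 ms, peak at 323.7 ms),
summed linearly over events, multiplied by the rectification
`G_rect(V) = 0.2/(1 + exp(0.05(V − V_GIRK)))` μS/mm². V_GIRK defaults to
the neuron's potassium reversal (−85 mV): GIRK is a potassium channel
and no separate reversal measurement constrains the model. In the
engine, each directed connection keeps two exponential accumulators
(the ODE form of the kernel sum), which reproduces the analytic event
sum to machine precision and costs O(1) per step.

**Unit coupling and gain.** G_rect's native μS/mm² convert to mS/cm²
by 0.1. The remaining dimensionless weight (`GIRKParams.gain`, default
3.75, times S_ij = 1) absorbs receptor density and the geometry of the
release-site apposition, none of which are measured. It was calibrated
once against the autoinhibition behaviour: after a 1 s, ~20 Hz bout the
pacemaker should stay silent for several hundred milliseconds, while
its firing *during* the bout stays within 10% of a GIRK-free control.
gain = 3.75 gives a post-step quiescence of ≈ 0.42 s (median over ten
seeds; GIRK-free control ≈ 0.24 s, the intrinsic AHP-recovery time) at a
−6% in-step rate change. Larger gains lengthen the quiescence towards
0.5 s but push the in-step suppression past 10%; the shipped value
favours keeping both properties, and the residual shortfall against the
nominal half-second quiescence is a consequence of this calibration
trade-off, not of the kernel.

In the dendro-somatic scenario the same conductance fully silences the
connected resting neuron from ≈ 0.6 s into the presynaptic step (the
release-fraction gating plus the 324 ms kernel rise allow one early
escape spike) until a few hundred milliseconds after it ends.

## 3. Volume transmission

A quantal release is the point-source Green's function with optional
first-order clearance:

    C(r,t) = C0 (t0/t)^{3/2} exp(−r²/4Dt − k_up t),

D = 0.34 μm²/ms (3.4×10⁻⁶ cm²/s).

**Source calibration.** The Green's function is singular at t → 0, so
the quantal concentration C0 = 200 nM must be attached to a reference.
The released bolus is treated as a Gaussian whose centre concentration
equals C0 once its RMS radius reaches an effective source radius
a = 4 μm (t0 = a²/4D ≈ 11.8 ms) — a perisomatic shell about half a soma
radius, consistent with a near-membrane amperometric measurement. Under
this calibration the far field shows C/C0 ≈ 1.0–1.7×10⁻³ at 20–25 μm
over 200–800 ms, and the occupancy and kernel numbers below follow with
no further freedom. The reference is configurable and recorded in
output metadata.

**Reuptake.** `k_up` defaults to 0. A literature clearance of 20 s⁻¹ is
kept as a named constant (`REUPTAKE_LITERATURE_PER_MS`) and honoured by
the equation (total mass then decays exactly as exp(−k_up t), which is
tested), but it is not the default because transporter activity in the
LC core is argued to be non-limiting, and a 20 s⁻¹ clearance would
multiply the 500 ms far field by e⁻¹⁰ ≈ 5×10⁻⁵, extinguishing volume
transmission entirely: no neighbour interaction, sub-percent receptor
occupancy. The model of interest — measurable bystander inhibition
within 25 μm — exists only in the slow-clearance regime.

**Binding.** The bound alpha2 fraction integrates
`τ(C) dx/dt = −x + x_eq(C)` with x_eq = C·k_on/(C·k_on + k_off),
τ = 1/(C·k_on + k_off), k_on = 1 nM⁻¹s⁻¹, k_off = 1.25 s⁻¹
(K_D = 1.25 nM), with C evaluated per time step (exact exponential
update within the step). Peak occupancy from one quantal release:
≈ 0.29 at 10 μm, ≈ 0.17 at 20 μm, ≈ 0.12 at 25 μm.

**Effective kernel.** The conductance drive a neighbour receives from
one release is occupancy → 50 ms alpha filter (transmitter
binding/unbinding smoothing) → unit-area GIRK machinery kernel (the
normalized synaptic double exponential, representing the G-protein
cascade that acts identically regardless of how NE arrived). On the
synaptic-kernel scale (saturating synaptic event ≡ peak 1), the fitted
double exponential at 25 μm has amplitude ≈ 0.08 and nearly degenerate
time constants ≈ 1.83 s, peaking ≈ 1.9 s after the release — an order
of magnitude weaker and five-fold slower than the synaptic kernel.
Fitting the occupancy directly (without the machinery stage) changes
the amplitude little but leaves the two time constants on an
unidentifiable ridge; the full chain is both the physically complete
statement and the better-conditioned fit. In network simulations each
volume connection uses this fitted kernel (computed once per distance
and cached), so volume events superpose linearly like synaptic ones.

**Onset delay.** The neighbour's conductance in a single-step volume
scenario peaks ≈ 1.2 s later than the postsynaptic conductance in the
matched dendro-somatic scenario (≈ 1.6 s at the kernel level). The
delay is reported as this peak-time difference: a threshold-crossing
definition ("first exceeds 10% of peak") is not meaningful for kernels
of this family, which leave zero smoothly and cross any fixed fraction
of their peak within tens of milliseconds even when the bulk of the
conductance arrives seconds later.

**Decay constant.** After a stimulated release train ends, the summed
kernel's log-slope approaches 1/τ_slow only beyond the separation time
τ_f τ_s/(τ_s − τ_f) = 2.1 s. The decay fit therefore uses a log-linear
fit over a window 3–6 s after the last event, returning ≈ 357 ms for
the default kernel; earlier windows mix the two exponentials and
overestimate τ by 15–30%.

## 4. Synthetic LC geometry

The generator emulates the pooled statistics of four segmented nuclei:
for each nucleus, 289 somata in an ellipsoid of semi-axes
(720, 300, 300) μm; 82% placed uniformly, 18% placed as "satellites"
21–28 μm from a random parent cell. The satellite component supplies
the short-range clustering a homogeneous Poisson process cannot
produce: with the measured median (~41 μm) a Poisson process would put
only ~14% of cells within 25 μm and peak the NN histogram near 40 μm,
whereas the measured data show ~25% and a 24–28 μm mode. Across twenty
seeds the pooled clouds give mean NN median ≈ 42 μm, sub-25 μm fraction
≈ 25%, mode bin 24–28 μm in ≥ 85% of cohorts. Coordinates are isotropic
μm (an optional z-scale flag exists for anisotropic light-sheet
sampling; no correction is applied by default).

The NN-distance histogram (4 μm bins) is fitted with
`f(d) = A [exp(−d/λ_long) − exp(−d/λ_short)]^γ`. Because the two length
constants are nearly equal, the family reduces over the data range to
`(d/λ*)^γ exp(−γ d/λ_long)` and the gap λ_long/λ_short is statistically
unidentifiable; the fitter profiles (A, γ, λ_long) at a fixed gap ratio
(default 16.84/16.23, the shipped family; `free_gap=True` releases it).
Parameter recovery on self-generated samples (n = 1200) is then
unbiased to ~1%. Note that the shipped family parameters and the
summary statistics are different views: a cloud matching the measured
median cannot simultaneously reproduce a fitted λ_long of ~17 μm, and
both are therefore reported side by side rather than forced to agree.

What the synthetic clouds do **not** model: anisotropic nucleus shape
variation between animals, segmentation false negatives/positives, the
dorsoventral density gradient, and soma size/sphericity (accepted as
optional input columns only). Calibration checks passing on these
clouds establish that the analysis pipeline is correct and that the
generator matches the pooled summary statistics — not that real LC
geometry is a two-component cluster process.

## 5. Numerics and determinism

* Fixed-step integration, default dt = 0.025 ms: explicit Euler for
  voltages, exponential (exact frozen-coefficient) updates for gating,
  calcium and the kernel accumulators. Convergence is first order in
  dt (tested by step-halving); spike times shift by < 1 ms when dt is
  halved.
* Numerical blow-up (non-finite state) raises an error naming the
  neuron and time; the IEEE error model is used inside the JIT kernel
  so overflow propagates to the check rather than trapping.
* Traces are sampled at 1 kHz for storage; spike detection runs at
  integration resolution inside the engine.
* One run seed drives all noise; every per-part seed in scripts and
  fixtures is derived arithmetically from it, so results are
  reproducible bit-for-bit for a given configuration hash (recorded,
  with file hashes, in the run manifest).
* Scenario durations used by the shipped measurements: 60 s for
  spontaneous-rate estimates, 5 s for synaptic/autoinhibition
  scenarios, 9–12 s for volume scenarios (the slow kernel needs the
  tail), 20 replicate cohorts for geometry statistics.

## 6. Known limitations

* The HH rate functions are inherited surrogates tuned at the
  population-behaviour level; AP-waveform details (threshold, exact
  width) should not be over-interpreted.
* Autoinhibition calibration trades in-step rate stability against
  post-step quiescence (section 2 above); the shipped gain leaves the quiescence
  ≈ 0.42 s rather than the nominal half second.
* Volume transmission assumes an isotropic, tortuosity-free medium,
  linear superposition between sources, no transporter saturation, and
  no receptor desensitization.
* The dendritic compartment is a single passive cylinder; no dendritic
  release sites or multi-compartment morphology.
* Vesicle pools do not deplete; co-released transmitters are out of
  scope.
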