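"""Fixed-step network integrator (numba).

State layout per neuron: [v_s, v_d, m, h, n, ca].  Neuron parameters are
packed row-wise into a float array with the column order given by the
IP_* constants.  Synaptic/volume GIRK kernels are represented by two
exponential state variables per directed pair (a_slow, a_fast), which is
the exact ODE form of the event-sum double-exponential kernel: on each
presynaptic spike both accumulators are incremented by the release
fraction, and the pair drive is B*(a_slow - a_fast).
"""

import numpy as np
from numba import njit

# neuron parameter columns
(IP_CM, IP_GNA, IP_GK, IP_GP, IP_GAHP, IP_GCA, IP_GL, IP_GLD, IP_GC,
 IP_VNA, IP_VK, IP_VCA, IP_VL, IP_VLD, IP_KSHIFT, IP_PHALF, IP_PSLOPE,
 IP_MCA, IP_TAUCA, IP_KHALF) = range(20)

N_PARAM = 20

SPIKE_THRESHOLD = 0.0   # mV, upward crossing
REFRACTORY_MS = 2.0


def pack_params(plist):
    """Pack a sequence of NeuronParams into the engine parameter matrix."""
    P = np.empty((len(plist), N_PARAM))
    for i, p in enumerate(plist):
        P[i] = (p.c_m, p.g_na, p.g_k, p.g_p, p.g_ahp, p.g_ca, p.g_l,
                p.g_ld, p.g_c, p.v_na, p.v_k, p.v_ca, p.v_l, p.v_ld,
                p.k_shift, p.p_half, p.p_slope, p.m_ca, p.tau_ca,
                p.ahp_k_half)
    return P


@njit(cache=True, error_model="numpy")
def _integrate(P, x0, stim, noise, gj_w, dt, sample_every,
               pair_pre, pair_post, pair_amp, pair_ef, pair_es, pair_b,
               ca_high, k_rel, rel_threshold,
               v_girk, rect_scale, rect_slope, girk_gain):
    """Integrate the network; returns traces, spikes, release log.

    stim, noise: (n, nsteps) current densities.
    gj_w: (n, n) gap-junction conductance matrix (dendro-dendritic).
    pair_*: directed GIRK connections; pair_amp carries S_ij (and, for
    volume pairs, the distance attenuation); pair_ef/es are per-step
    exponential decay factors; pair_b the peak normalization.
    Returns err_t < 0 on success, else the blow-up time.
    """
    n = P.shape[0]
    nsteps = stim.shape[1]
    npairs = pair_pre.shape[0]
    nsamp = (nsteps + sample_every - 1) // sample_every

    vs = x0[:, 0].copy()
    vd = x0[:, 1].copy()
    m = x0[:, 2].copy()
    h = x0[:, 3].copy()
    nn = x0[:, 4].copy()
    ca = x0[:, 5].copy()

    a_s = np.zeros(npairs)
    a_f = np.zeros(npairs)

    traces = np.zeros((nsamp, n, 4))
    max_spk = n * (int(nsteps * dt / REFRACTORY_MS) + 2)
    spk_t = np.empty(max_spk)
    spk_id = np.empty(max_spk, dtype=np.int64)
    nspk = 0
    rel_t = np.empty(max_spk)
    rel_id = np.empty(max_spk, dtype=np.int64)
    rel_ca = np.empty(max_spk)
    rel_w = np.empty(max_spk)
    nrel = 0
    last_spike = np.full(n, -1.0e9)
    g_eff = np.zeros(n)

    err_t = -1.0
    err_neuron = -1

    for istep in range(nsteps):
        t = istep * dt

        # per-neuron rectified GIRK conductance density (mS/cm^2)
        for i in range(n):
            g_eff[i] = 0.0
        for p in range(npairs):
            drive = pair_b[p] * (a_s[p] - a_f[p])
            if drive > 0.0:
                g_eff[pair_post[p]] += pair_amp[p] * drive
        for i in range(n):
            grect = rect_scale / (1.0 + np.exp(rect_slope * (vs[i] - v_girk)))
            g_eff[i] *= 0.1 * girk_gain * grect   # uS/mm^2 -> mS/cm^2

        if istep % sample_every == 0:
            ks = istep // sample_every
            for i in range(n):
                traces[ks, i, 0] = vs[i]
                traces[ks, i, 1] = vd[i]
                traces[ks, i, 2] = ca[i]
                traces[ks, i, 3] = g_eff[i]

        for i in range(n):
            v = vs[i]
            vt = v + 60.0
            # HH rates (classic, -60 mV reference); rectifier shifted
            d = 25.0 - vt
            if abs(d) > 1e-9:
                am = 0.1 * d / (np.exp(d / 10.0) - 1.0)
            else:
                am = 1.0
            bm = 4.0 * np.exp(-vt / 18.0)
            ah = 0.07 * np.exp(-vt / 20.0)
            bh = 1.0 / (np.exp((30.0 - vt) / 10.0) + 1.0)
            vn = vt - P[i, IP_KSHIFT]
            d = 10.0 - vn
            if abs(d) > 1e-9:
                an = 0.01 * d / (np.exp(d / 10.0) - 1.0)
            else:
                an = 0.1
            bn = 0.125 * np.exp(-vn / 80.0)

            i_na = P[i, IP_GNA] * m[i] ** 3 * h[i] * (v - P[i, IP_VNA])
            i_k = P[i, IP_GK] * nn[i] ** 4 * (v - P[i, IP_VK])
            pinf = 1.0 / (1.0 + np.exp(-(v - P[i, IP_PHALF]) / P[i, IP_PSLOPE]))
            i_p = P[i, IP_GP] * pinf * (v - P[i, IP_VNA])
            r = ca[i] / (ca[i] + P[i, IP_KHALF])
            i_ahp = P[i, IP_GAHP] * r * (v - P[i, IP_VK])
            i_ca = P[i, IP_GCA] * (v - P[i, IP_VCA])
            i_girk = g_eff[i] * (v - v_girk)
            i_dend = P[i, IP_GC] * (v - vd[i])
            i_l = P[i, IP_GL] * (v - P[i, IP_VL])

            dv_s = (stim[i, istep] - i_na - i_k - i_p - i_ahp - i_ca
                    - i_girk - i_dend - i_l + noise[i, istep]) / P[i, IP_CM]

            i_gj = 0.0
            for j in range(n):
                if gj_w[i, j] != 0.0:
                    i_gj += gj_w[i, j] * (vd[i] - vd[j])
            i_soma = P[i, IP_GC] * (vd[i] - v)
            i_ld = P[i, IP_GLD] * (vd[i] - P[i, IP_VLD])
            dv_d = -(i_soma + i_gj + i_ld) / P[i, IP_CM]

            vs_new = v + dt * dv_s
            vd_new = vd[i] + dt * dv_d

            # gating / calcium: exponential updates at frozen voltage
            tm = 1.0 / (am + bm)
            m[i] = am * tm + (m[i] - am * tm) * np.exp(-dt / tm)
            th = 1.0 / (ah + bh)
            h[i] = ah * th + (h[i] - ah * th) * np.exp(-dt / th)
            tn = 1.0 / (an + bn)
            nn[i] = an * tn + (nn[i] - an * tn) * np.exp(-dt / tn)
            cinf = (P[i, IP_MCA] / 132.6) * (P[i, IP_VCA] - v) / \
                (1.0 + np.exp(-(v + 25.0) / 2.5))
            ca_at_spike = ca[i]
            ca[i] = cinf + (ca[i] - cinf) * np.exp(-dt / P[i, IP_TAUCA])
            if ca[i] < 0.0:
                ca[i] = 0.0

            if v < SPIKE_THRESHOLD <= vs_new and \
                    t - last_spike[i] > REFRACTORY_MS:
                last_spike[i] = t
                spk_t[nspk] = t
                spk_id[nspk] = i
                nspk += 1
                w = 2.0 * ca_at_spike ** k_rel / \
                    (ca_high ** k_rel + ca_at_spike ** k_rel)
                if rel_threshold >= 0.0 and ca_at_spike < rel_threshold:
                    w = 0.0
                rel_t[nrel] = t
                rel_id[nrel] = i
                rel_ca[nrel] = ca_at_spike
                rel_w[nrel] = w
                nrel += 1
                for p in range(npairs):
                    if pair_pre[p] == i:
                        a_s[p] += w
                        a_f[p] += w

            vs[i] = vs_new
            vd[i] = vd_new

            if not (np.isfinite(vs[i]) and np.isfinite(vd[i])):
                err_t = t
                err_neuron = i
                break
        if err_t >= 0.0:
            break

        # kernel state decay
        for p in range(npairs):
            a_s[p] *= pair_es[p]
            a_f[p] *= pair_ef[p]

    x_out = np.empty((n, 6))
    for i in range(n):
        x_out[i, 0] = vs[i]
        x_out[i, 1] = vd[i]
        x_out[i, 2] = m[i]
        x_out[i, 3] = h[i]
        x_out[i, 4] = nn[i]
        x_out[i, 5] = ca[i]

    return (traces, spk_t[:nspk], spk_id[:nspk],
            rel_t[:nrel], rel_id[:nrel], rel_ca[:nrel], rel_w[:nrel],
            x_out, err_t, err_neuron)
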