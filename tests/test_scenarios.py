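"""Network scenarios: validation protocols and the three interaction modes."""

import numpy as np
import pytest

from lcnet.core import IntegrationError
from lcnet.network import (NetworkConfig, Wire, conductance_peak_time,
                           dendro_somatic_pair, fi_protocol,
                           first_spike_after, run_scenario,
                           run_volume_scenario, volume_scenario)
from lcnet.params import (GIRKParams, NeuronParams, ParameterError,
                          StimulusProtocol)


class TestConfig:
    def test_wire_validation(self):
        with pytest.raises(ParameterError):
            Wire(0, 1, "autoinhibition")          # must be diagonal
        with pytest.raises(ParameterError):
            Wire(0, 1, "volume")                  # needs a distance
        with pytest.raises(ParameterError):
            Wire(0, 1, "dendro_somatic", strength=-1.0)

    def test_endpoints_checked(self):
        with pytest.raises(ParameterError):
            NetworkConfig(neurons=[NeuronParams()],
                          wires=[Wire(0, 3, "dendro_somatic")])

    def test_protocol_overlap_rejected(self):
        with pytest.raises(ParameterError):
            StimulusProtocol(steps=((0.0, 100.0, 1.0), (50.0, 100.0, 1.0)))


class TestReproducibility:
    def test_identical_config_and_seed_identical_result(self, step_amp):
        a = run_scenario(dendro_somatic_pair(step_amp, seed=9,
                                             duration_ms=3000.0))
        b = run_scenario(dendro_somatic_pair(step_amp, seed=9,
                                             duration_ms=3000.0))
        for i in range(2):
            np.testing.assert_array_equal(a.spikes[i], b.spikes[i])
        np.testing.assert_array_equal(a.v_s, b.v_s)
        assert a.metadata["config_hash"] == b.metadata["config_hash"]

    def test_spike_times_strictly_increasing(self, dendro_result):
        for s in dendro_result.spikes:
            assert np.all(np.diff(s) > 0)

    def test_blowup_names_neuron_and_time(self, step_amp):
        cfg = dendro_somatic_pair(step_amp * 50, noise=False,
                                  duration_ms=2000.0)
        cfg.dt_ms = 2.5
        with pytest.raises(IntegrationError, match="neuron"):
            run_scenario(cfg)


class TestSpontaneousPair:
    def test_unconnected_pair_fires_independently(self):
        cfg = NetworkConfig(neurons=[NeuronParams(), NeuronParams()],
                            duration_ms=20000.0, seed=3)
        res = run_scenario(cfg)
        for i in range(2):
            assert res.rate(i) == pytest.approx(4.3, abs=0.4)
        # no interaction: spike trains should not be phase locked
        d = np.abs(res.spikes[0][:, None] - res.spikes[1][None, :]).min(1)
        assert np.median(d) > 5.0


class TestCausality:
    def test_no_conductance_before_first_release(self, dendro_result):
        res = dendro_result
        t_first = res.releases["t_ap_ms"].min()
        sel = res.time_ms < t_first
        assert np.all(res.g_girk[1][sel] == 0.0)


class TestDendroSomatic:
    def test_n2_silenced_late_step_and_resumes(self, dendro_result):
        """Once the release-gated conductance builds up, the connected
        neuron is silent through the rest of the step and past its end,
        resuming only after the conductance decays."""
        n2 = dendro_result.spikes[1]
        assert np.sum((n2 >= 1700.0) & (n2 < 2300.0)) == 0
        lat = first_spike_after(dendro_result, 1, 2000.0)
        assert lat > 250.0    # longer than the free ISI of ~233 ms

    def test_ordering_and_n1_not_silenced(self, dendro_result,
                                          dendro_result_girk_off):
        assert len(dendro_result.spikes[1]) <= \
            len(dendro_result_girk_off.spikes[1])
        assert dendro_result.rate(0, 1000.0, 2000.0) >= 18.0

    def test_decay_tau_350ms(self, dendro_result):
        from lcnet.neuromod import girk_decay_tau
        t_ap, w = dendro_result.release_events(0)
        step = (t_ap >= 1000.0) & (t_ap < 2000.0)
        tau = girk_decay_tau(t_ap[step], w[step])
        assert tau == pytest.approx(350.0, abs=20.0)


class TestAutoinhibition:
    def test_rate_kept_but_quiescence_follows(self, auto_results):
        on, off = auto_results
        rate_on = np.mean([r.rate(0, 1000.0, 2000.0) for r in on])
        rate_off = np.mean([r.rate(0, 1000.0, 2000.0) for r in off])
        assert abs(rate_on / rate_off - 1.0) < 0.10
        lat_on = np.median([first_spike_after(r, 0, 2000.0) for r in on])
        lat_off = np.median([first_spike_after(r, 0, 2000.0) for r in off])
        assert lat_off < 250.0
        assert lat_on == pytest.approx(500.0, abs=150.0)
        assert lat_on > lat_off + 100.0


class TestVolume:
    def test_onset_delayed_vs_dendro(self, volume_single, dendro_result):
        tp_vol = conductance_peak_time(volume_single, 1)
        tp_den = conductance_peak_time(dendro_result, 1)
        delay = tp_vol - tp_den
        assert delay == pytest.approx(1400.0, abs=300.0)

    def test_accumulation_across_steps(self, volume_single, volume_double):
        t = volume_double.time_ms
        g = volume_double.g_girk[1]
        g1 = g[(t >= 1000.0) & (t < 4000.0)].max()
        g2 = g[t >= 4000.0].max()
        assert g2 > g1 * 1.2
        # and the second peak exceeds the single-step scenario peak
        assert g2 > volume_single.g_girk[1].max() * 1.2

    def test_shorter_gap_larger_accumulation(self, step_amp):
        short = run_scenario(volume_scenario(
            step_amp, onsets_ms=(1000.0, 3000.0), duration_ms=10000.0,
            noise=False))
        long = run_scenario(volume_scenario(
            step_amp, onsets_ms=(1000.0, 5000.0), duration_ms=12000.0,
            noise=False))
        t_s, g_s = short.time_ms, short.g_girk[1]
        t_l, g_l = long.time_ms, long.g_girk[1]
        assert g_s[t_s >= 3000.0].max() > g_l[t_l >= 5000.0].max()

    def test_partitioning_by_distance(self, step_amp):
        """Driven neuron unchanged, 25 um neighbour ISI lengthened,
        100 um control neighbour unaffected (<5%)."""
        res = run_scenario(volume_scenario(
            step_amp, onsets_ms=(1000.0, 4000.0), duration_ms=12000.0,
            seed=2, control_distance_um=100.0))
        base = run_scenario(NetworkConfig(
            neurons=[NeuronParams()], duration_ms=12000.0, seed=2))

        def med_isi(spk, t0, t1):
            s = spk[(spk >= t0) & (spk < t1)]
            return np.median(np.diff(s))

        free = med_isi(base.spikes[0], 2000.0, 12000.0)
        isi_n3 = med_isi(res.spikes[1], 2000.0, 12000.0)
        isi_ctrl = med_isi(res.spikes[2], 2000.0, 12000.0)
        assert isi_n3 > free * 1.03
        assert abs(isi_ctrl / free - 1.0) < 0.05
        # driven neuron keeps its in-step rate (no self-inhibition wired)
        assert res.rate(0, 1000.0, 2000.0) >= 18.0

    def test_run_volume_scenario_requires_volume_wire(self, step_amp):
        with pytest.raises(ParameterError):
            run_volume_scenario(dendro_somatic_pair(step_amp))


@pytest.fixture(scope="module")
def fi():
    return fi_protocol(amplitudes=np.arange(0.0, 51.0, 10.0))


class TestFICurve:
    def test_zero_amplitude_is_spontaneous(self, fi):
        assert fi["rate_hz"].iloc[0] == pytest.approx(4.3, abs=3.0)

    def test_rates_nondecreasing(self, fi):
        assert np.all(np.diff(fi["rate_hz"].to_numpy()) >= 0.0)

    def test_early_rate_exceeds_mean_and_gap_widens(self, fi):
        # spike-frequency adaptation through calcium/AHP accumulation:
        # the effect is pronounced at the higher current amplitudes
        sub = fi[fi["amplitude"] >= 30.0]
        gap = sub["early_rate_hz"] - sub["rate_hz"]
        assert np.all(gap > 0.0)
        assert np.all(np.diff(gap) > 0.0)
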