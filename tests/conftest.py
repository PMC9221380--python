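"""Shared fixtures.

Heavy simulations are session-scoped so the JIT-compiled engine and the
calibrated step amplitude are reused across test modules.
"""

import numpy as np
import pytest

from lcnet.network import (autoinhibition_scenario, calibrate_step_amplitude,
                           dendro_somatic_pair, run_scenario, volume_scenario)


@pytest.fixture(scope="session")
def step_amp():
    """Current-step density calibrated to drive the neuron at ~20 Hz."""
    return calibrate_step_amplitude()


@pytest.fixture(scope="session")
def spont_results():
    """Five 60 s spontaneous runs (noise on, seeds 1..5)."""
    from lcnet.network import simulate_neuron
    return [simulate_neuron(duration_ms=60000.0, seed=s) for s in range(1, 6)]


@pytest.fixture(scope="session")
def dendro_result(step_amp):
    """Deterministic dendro-somatic pair scenario (N1 driven 1 s)."""
    return run_scenario(dendro_somatic_pair(step_amp, noise=False))


@pytest.fixture(scope="session")
def dendro_result_girk_off(step_amp):
    return run_scenario(dendro_somatic_pair(step_amp, noise=False,
                                            girk_on=False))


@pytest.fixture(scope="session")
def auto_results(step_amp):
    """Autoinhibition scenario over 10 noise seeds, plus GIRK-off controls."""
    on = [run_scenario(autoinhibition_scenario(step_amp, seed=s))
          for s in range(1, 11)]
    off = [run_scenario(autoinhibition_scenario(step_amp, seed=s,
                                                girk_on=False))
           for s in range(1, 11)]
    return on, off


@pytest.fixture(scope="session")
def volume_single(step_amp):
    """Volume scenario, single 1 s step, neighbour at 25 um, no noise."""
    return run_scenario(volume_scenario(step_amp, onsets_ms=(1000.0,),
                                        duration_ms=9000.0, noise=False))


@pytest.fixture(scope="session")
def volume_double(step_amp):
    """Volume scenario, two 1 s steps separated by 2 s, no noise."""
    return run_scenario(volume_scenario(step_amp, onsets_ms=(1000.0, 4000.0),
                                        duration_ms=12000.0, noise=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
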