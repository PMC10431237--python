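import numpy as np
import pytest

from retinophys import synth
from retinophys.stimulus import StimulusSpec


@pytest.fixture
def spot_stimulus():
    return StimulusSpec(kind="spot", diameter=175.0, onset=0.2, offset=0.7)


@pytest.fixture
def boxcar_waveforms(spot_stimulus):
    """Shared (g_exc, g_inh) templates: transient+sustained exc, boxcar inh."""
    n, dt = 1000, 1e-3
    g_exc = synth.boxcar_with_transient(n, dt, 0.2, 0.7, sustained=0.75,
                                        transient=1.0, transient_tau=0.05)
    g_inh = synth.boxcar_with_transient(n, dt, 0.2, 0.7, sustained=1.0)
    return g_exc, g_inh, dt


@pytest.fixture
def noiseless_family(boxcar_waveforms, spot_stimulus):
    g_exc, g_inh, dt = boxcar_waveforms
    params = synth.VClampSimParams(g_exc_waveform=g_exc, g_inh_waveform=g_inh,
                                   noise_sd=0.0, sampling_interval=dt,
                                   seed=0, stimulus=spot_stimulus)
    return synth.simulate_vclamp_family(params)
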