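import numpy as np
import pytest

from retinophys import synth, vclamp as vc
from retinophys.stimulus import StimulusSpec
from retinophys.vclamp import (ConductanceModel, ConductanceTrace,
                               CurrentTrace, VClampFamily,
                               apply_junction_correction, decompose_conductance,
                               leak_iv, net_evoked_currents, peak_conductance,
                               subtract_conductance)


def make_family(currents_by_v, dt=1e-3, stimulus=None, baseline=None):
    traces = [CurrentTrace(np.asarray(i, float), dt, v, stimulus)
              for v, i in currents_by_v.items()]
    return VClampFamily(traces=traces, baseline_window=baseline)


class TestJunctionCorrection:
    def test_shifts_all_potentials(self):
        fam = make_family({-80.0: np.zeros(200), 40.0: np.zeros(200)})
        out = apply_junction_correction(fam, -10.0)
        assert sorted(out.holding_potentials) == [-90.0, 30.0]
        assert out.junction_applied

    def test_zero_is_identity(self):
        fam = make_family({-80.0: np.zeros(200), 40.0: np.zeros(200)})
        out = apply_junction_correction(fam, 0.0)
        assert np.array_equal(out.holding_potentials, fam.holding_potentials)

    def test_double_application_rejected(self):
        fam = make_family({-80.0: np.zeros(200), 40.0: np.zeros(200)})
        out = apply_junction_correction(fam)
        with pytest.raises(ValueError, match="already applied"):
            apply_junction_correction(out)


class TestLeakIV:
    def test_recovers_simulated_leak_line(self):
        z = np.zeros(500)
        p = synth.VClampSimParams(g_exc_waveform=z, g_inh_waveform=z,
                                  g_leak=2.0, e_leak=-60.0, noise_sd=0.0)
        fam, _ = synth.simulate_vclamp_family(p)
        iv = leak_iv(fam)
        assert iv.slope == pytest.approx(2.0)
        assert iv.reversal == pytest.approx(-60.0)
        assert iv.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_zero_current_family_flagged_degenerate(self):
        fam = make_family({-90.0: np.zeros(500), 50.0: np.zeros(500)})
        iv = leak_iv(fam)
        assert iv.slope == 0.0
        assert np.isnan(iv.reversal)
        assert iv.degenerate

    def test_noisy_leak_slope_within_3se(self):
        z = np.zeros(500)
        slopes = []
        for seed in range(30):
            p = synth.VClampSimParams(g_exc_waveform=z, g_inh_waveform=z,
                                      g_leak=2.0, e_leak=-60.0,
                                      noise_sd=5.0, seed=seed)
            fam, _ = synth.simulate_vclamp_family(p)
            slopes.append(leak_iv(fam).slope)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 2.0) < 3 * se

    def test_baseline_overlapping_stimulus_rejected(self):
        stim = StimulusSpec(kind="spot", onset=0.05, offset=0.2)
        fam = make_family({-90.0: np.zeros(500), 50.0: np.zeros(500)},
                          stimulus=stim, baseline=(0.0, 0.1))
        with pytest.raises(ValueError, match="overlaps"):
            leak_iv(fam)


class TestNetEvokedCurrents:
    def test_silent_family_gives_zero_net(self, noiseless_family):
        fam, _ = noiseless_family
        z = np.zeros_like(fam.traces[0].samples)
        p = synth.VClampSimParams(g_exc_waveform=z, g_inh_waveform=z,
                                  g_leak=3.0, e_leak=-55.0, noise_sd=0.0)
        silent, _ = synth.simulate_vclamp_family(p)
        net = net_evoked_currents(silent)
        assert np.allclose(net.currents, 0.0)

    def test_excitation_reverses_at_zero_mv(self):
        g = np.zeros(1000)
        g[300:600] = 1.0
        p = synth.VClampSimParams(g_exc_waveform=g,
                                  g_inh_waveform=np.zeros(1000),
                                  g_leak=2.0, e_leak=-60.0, noise_sd=0.0,
                                  holding_potentials=(-90.0, -20.0, 20.0))
        fam, _ = synth.simulate_vclamp_family(p)
        net = net_evoked_currents(fam)
        evoked = net.currents[:, 450]
        assert evoked[net.voltages < 0].max() < 0     # inward below reversal
        assert evoked[net.voltages > 0].min() > 0     # outward above

    def test_hand_computed_net_current(self):
        ones = np.ones(1000)
        ones[:100] = 0.0          # silent baseline region
        p = synth.VClampSimParams(g_exc_waveform=ones, g_inh_waveform=ones,
                                  g_leak=2.0, e_leak=-60.0, noise_sd=0.0,
                                  holding_potentials=(-90.0, 50.0))
        fam, _ = synth.simulate_vclamp_family(p)
        fam.baseline_window = (0.0, 0.1)
        net = net_evoked_currents(fam)
        i90 = net.currents[list(net.voltages).index(-90.0)]
        assert i90[500] == pytest.approx(-111.0)


class TestDecomposition:
    def test_two_point_exact_solve(self):
        # I(-90) = -111, I(+50) = 169 with reversals (0, -69) -> gE = gI = 1
        net = vc.NetEvokedCurrents(
            time=np.array([0.005]), voltages=np.array([-90.0, 50.0]),
            currents=np.array([[-111.0], [169.0]]), sampling_interval=0.01)
        tr = decompose_conductance(net, interval=0.01)
        assert tr.g_exc[0] == pytest.approx(1.0)
        assert tr.g_inh[0] == pytest.approx(1.0)

    def test_roundtrip_exact_at_zero_noise(self, noiseless_family,
                                           boxcar_waveforms):
        fam, truth = noiseless_family
        g_exc, g_inh, dt = boxcar_waveforms
        tr = decompose_conductance(net_evoked_currents(fam))
        # compare against the bin-averaged ground truth
        per = int(round(0.01 / dt))
        nb = g_exc.size // per
        ge_true = g_exc[:nb * per].reshape(nb, per).mean(axis=1)
        gi_true = g_inh[:nb * per].reshape(nb, per).mean(axis=1)
        assert np.allclose(tr.g_exc, ge_true, atol=1e-10)
        assert np.allclose(tr.g_inh, gi_true, atol=1e-10)
        assert np.max(tr.fit_residual_rms) < 1e-9

    def test_roundtrip_any_two_potentials(self, boxcar_waveforms):
        g_exc, g_inh, dt = boxcar_waveforms
        p = synth.VClampSimParams(g_exc_waveform=g_exc, g_inh_waveform=g_inh,
                                  noise_sd=0.0, sampling_interval=dt,
                                  holding_potentials=(-49.0, -31.0))
        fam, _ = synth.simulate_vclamp_family(p)
        tr = decompose_conductance(net_evoked_currents(fam))
        per = int(round(0.01 / dt))
        nb = g_exc.size // per
        ge_true = g_exc[:nb * per].reshape(nb, per).mean(axis=1)
        assert np.allclose(tr.g_exc, ge_true, atol=1e-9)

    def test_single_component_limit(self, boxcar_waveforms):
        g_exc, _, dt = boxcar_waveforms
        p = synth.VClampSimParams(g_exc_waveform=g_exc,
                                  g_inh_waveform=np.zeros_like(g_exc),
                                  noise_sd=0.0, sampling_interval=dt)
        fam, _ = synth.simulate_vclamp_family(p)
        tr = decompose_conductance(net_evoked_currents(fam))
        assert np.allclose(tr.g_inh, 0.0, atol=1e-10)

    def test_residual_grows_with_noise(self, boxcar_waveforms):
        g_exc, g_inh, dt = boxcar_waveforms
        rms = []
        for noise in (0.0, 2.0, 8.0):
            p = synth.VClampSimParams(g_exc_waveform=g_exc,
                                      g_inh_waveform=g_inh, noise_sd=noise,
                                      sampling_interval=dt, seed=11)
            fam, _ = synth.simulate_vclamp_family(p)
            tr = decompose_conductance(net_evoked_currents(fam))
            rms.append(np.mean(tr.fit_residual_rms))
        assert rms[0] < rms[1] < rms[2]

    def test_unbiased_peak_under_noise(self, boxcar_waveforms):
        g_exc, g_inh, dt = boxcar_waveforms
        peaks = []
        for seed in range(50):
            p = synth.VClampSimParams(g_exc_waveform=g_exc,
                                      g_inh_waveform=g_inh, noise_sd=4.0,
                                      sampling_interval=dt, seed=seed)
            fam, _ = synth.simulate_vclamp_family(p)
            tr = decompose_conductance(net_evoked_currents(fam))
            peaks.append(tr.g_exc.max())
        per = int(round(0.01 / dt))
        nb = g_exc.size // per
        true_peak = g_exc[:nb * per].reshape(nb, per).mean(axis=1).max()
        se = np.std(peaks, ddof=1) / np.sqrt(len(peaks))
        assert abs(np.mean(peaks) - true_peak) < 3 * se

    def test_singular_design_rejected(self):
        net = vc.NetEvokedCurrents(
            time=np.array([0.0]), voltages=np.array([-90.0, 50.0]),
            currents=np.zeros((2, 1)), sampling_interval=0.01)
        with pytest.raises(ValueError):
            ConductanceModel(net, e_exc=-69.0, e_inh=-69.0)

    def test_results_summary_mentions_peaks(self, noiseless_family):
        fam, _ = noiseless_family
        res = ConductanceModel(net_evoked_currents(fam)).fit()
        s = res.summary()
        assert "peak_g_exc_nS" in s and "n_potentials" in s


class TestPeakAndSubtraction:
    def test_monotone_ramp_peaks_at_window_end(self):
        t = np.arange(10) * 0.01 + 0.005
        tr = ConductanceTrace(time=t, g_exc=np.linspace(0, 1, 10),
                              g_inh=np.zeros(10))
        val, when = peak_conductance(tr)["exc"]
        assert val == 1.0 and when == pytest.approx(t[-1])

    def test_all_zero_trace_ties_to_earliest(self):
        t = np.arange(10) * 0.01
        tr = ConductanceTrace(time=t, g_exc=np.zeros(10), g_inh=np.zeros(10))
        val, when = peak_conductance(tr)["exc"]
        assert val == 0.0 and when == 0.0

    def test_boxcar_peak_value(self):
        t = np.arange(20) * 0.01
        g = np.where((t >= 0.05) & (t < 0.15), 1.75, 0.0)
        tr = ConductanceTrace(time=t, g_exc=g, g_inh=np.zeros(20))
        assert peak_conductance(tr)["exc"][0] == pytest.approx(1.75)

    def test_empty_window_rejected(self):
        t = np.arange(10) * 0.01
        tr = ConductanceTrace(time=t, g_exc=np.zeros(10), g_inh=np.zeros(10))
        with pytest.raises(ValueError):
            peak_conductance(tr, (0.5, 0.6))

    def test_subtraction_identities(self):
        t = np.arange(10) * 0.01
        a = ConductanceTrace(time=t, g_exc=np.random.default_rng(0).random(10),
                             g_inh=np.zeros(10))
        b = ConductanceTrace(time=t, g_exc=np.random.default_rng(1).random(10),
                             g_inh=np.zeros(10))
        zero = subtract_conductance(a, a)
        assert np.allclose(zero.g_exc, 0.0)
        back = subtract_conductance(a, b)
        assert np.allclose(back.g_exc + b.g_exc, a.g_exc)

    def test_drug_subtraction_isolates_transient(self):
        t = np.arange(100) * 0.01
        sustained = np.where(t >= 0.2, 1.0, 0.0)
        transient = np.where(t >= 0.2, np.exp(-(t - 0.2) / 0.1), 0.0)
        control = ConductanceTrace(time=t, g_exc=np.zeros(100),
                                   g_inh=sustained + transient)
        drug = ConductanceTrace(time=t, g_exc=np.zeros(100), g_inh=sustained)
        diff = subtract_conductance(control, drug)
        assert np.allclose(diff.g_inh, transient)

    def test_time_base_mismatch_rejected(self):
        a = ConductanceTrace(time=np.arange(10) * 0.01, g_exc=np.zeros(10),
                             g_inh=np.zeros(10))
        b = ConductanceTrace(time=np.arange(10) * 0.02, g_exc=np.zeros(10),
                             g_inh=np.zeros(10))
        with pytest.raises(ValueError):
            subtract_conductance(a, b)

    def test_chain_is_linear(self, boxcar_waveforms):
        g_exc, g_inh, dt = boxcar_waveforms
        mk = lambda s: synth.simulate_vclamp_family(
            synth.VClampSimParams(g_exc_waveform=s * g_exc,
                                  g_inh_waveform=s * g_inh,
                                  noise_sd=0.0, sampling_interval=dt))[0]
        tr1 = decompose_conductance(net_evoked_currents(mk(1.0)))
        tr2 = decompose_conductance(net_evoked_currents(mk(2.0)))
        diff = subtract_conductance(tr2, tr1)
        assert np.allclose(diff.g_exc, tr1.g_exc, atol=1e-9)


def test_family_file_roundtrip(tmp_path, noiseless_family):
    fam, _ = noiseless_family
    path = tmp_path / "family.tsv"
    vc.write_family(path, fam)
    back = vc.read_family(path)
    assert np.allclose(back.holding_potentials, fam.holding_potentials)
    assert np.allclose(back.currents, fam.currents)
    assert back.stimulus.diameter == fam.stimulus.diameter


def test_conductance_file_roundtrip(tmp_path, noiseless_family):
    fam, _ = noiseless_family
    tr = decompose_conductance(net_evoked_currents(fam))
    path = tmp_path / "g.tsv"
    vc.write_conductance(path, tr)
    back = vc.read_conductance(path)
    assert np.allclose(back.g_exc, tr.g_exc)
    assert back.e_inh == tr.e_inh
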