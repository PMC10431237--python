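"""Synthetic-data generators with known ground truth.

Every input class the pipeline consumes can be generated here, so each
analysis stage is testable end to end without external recordings:

* voltage-clamp current families — leak plus *linear* excitatory and
  inhibitory synaptic conductances with fixed reversal potentials and
  Gaussian noise (the forward model of the inverse problem solved by
  :mod:`retinophys.vclamp`);
* continuous sEPSC records — homogeneous Poisson event trains of
  biexponential-decay kernels riding on slow low-pass baseline
  fluctuations plus white noise;
* DSGC spike rasters — inhomogeneous Poisson spiking with von Mises
  directional tuning of separate ON (trailing-edge) and OFF
  (leading-edge) components, Hill speed scaling (exponent 1) and a
  multiplicative wide-bar surround factor;
* two-channel IPL depth profiles — Gaussian bands over a baseline,
  with a two-band ChAT-like reference channel, plus a minimal TIFF
  stack writer to exercise image ingestion.

All generators take an integer seed and are bit-reproducible; a
pipeline-level master seed derives per-stage sub-seeds
deterministically (:func:`derive_seed`).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as ssignal

from .stimulus import StimulusSpec, weber_contrast
from .vclamp import (CurrentTrace, VClampFamily, ConductanceTrace,
                     DEFAULT_E_EXC, DEFAULT_E_INH)
from .tuning import SpikeRaster
from .ihc import DepthProfile, ImageStack

__all__ = [
    "derive_seed",
    "VClampSimParams", "simulate_vclamp_family",
    "SepscSimParams", "sepsc_kernel", "simulate_sepsc_trace",
    "DsgcSimParams", "drifting_bar_set", "simulate_dsgc_raster",
    "ProfileSimParams", "simulate_depth_profile", "profile_stack",
]

_SEED_MOD = 2 ** 31


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic per-stage sub-seed from a master seed and a label."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(label.encode())) % _SEED_MOD


# ---------------------------------------------------------------------------
# voltage clamp

def _default_holding_potentials() -> Tuple[float, ...]:
    return tuple(np.arange(-90.0, 50.0 + 1e-9, 20.0))


@dataclass
class VClampSimParams:
    """Forward model of a light-evoked voltage-clamp family.

    ``g_exc_waveform`` / ``g_inh_waveform`` are conductance-vs-time
    arrays (nS) on one shared time base at ``sampling_interval``.
    Holding potentials default to -90..+50 mV in 20-mV steps
    (junction-corrected values).
    """

    g_exc_waveform: np.ndarray
    g_inh_waveform: np.ndarray
    e_exc: float = DEFAULT_E_EXC
    e_inh: float = DEFAULT_E_INH
    g_leak: float = 2.0        # nS
    e_leak: float = -60.0      # mV
    holding_potentials: Tuple[float, ...] = field(
        default_factory=_default_holding_potentials)
    noise_sd: float = 0.0      # pA
    sampling_interval: float = 1e-3  # s
    seed: int = 0
    stimulus: Optional[StimulusSpec] = None

    def __post_init__(self):
        self.g_exc_waveform = np.asarray(self.g_exc_waveform, dtype=float)
        self.g_inh_waveform = np.asarray(self.g_inh_waveform, dtype=float)
        if self.g_exc_waveform.size != self.g_inh_waveform.size:
            raise ValueError("conductance waveforms must share one time base")
        v = np.asarray(self.holding_potentials, dtype=float)
        if v.size < 2 or np.any(np.diff(v) <= 0):
            raise ValueError("holding potentials must be strictly increasing, >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def boxcar_with_transient(n_samples: int, sampling_interval: float,
                          onset: float, offset: float,
                          sustained: float, transient: float = 0.0,
                          transient_tau: float = 0.05) -> np.ndarray:
    """A boxcar conductance with an optional exponentially decaying
    transient at onset — a convenient light-response template (nS)."""
    t = np.arange(n_samples) * sampling_interval
    g = np.zeros(n_samples)
    on = (t >= onset) & (t < offset)
    g[on] = sustained
    if transient:
        g[on] += transient * np.exp(-(t[on] - onset) / transient_tau)
    return g


def simulate_vclamp_family(params: VClampSimParams,
                           ) -> Tuple[VClampFamily, ConductanceTrace]:
    """Simulate I(t; V) = g_leak (V-E_leak) + g_E(t) (V-E_exc) + g_I(t) (V-E_inh) + noise.

    Returns the family and the ground-truth conductance trace (the
    input waveforms on the simulation time base).
    """
    rng = np.random.default_rng(params.seed)
    n = params.g_exc_waveform.size
    t = np.arange(n) * params.sampling_interval
    stim = params.stimulus
    traces = []
    for v in params.holding_potentials:
        i = (params.g_leak * (v - params.e_leak)
             + params.g_exc_waveform * (v - params.e_exc)
             + params.g_inh_waveform * (v - params.e_inh))
        if params.noise_sd > 0:
            i = i + rng.normal(0.0, params.noise_sd, size=n)
        traces.append(CurrentTrace(i, params.sampling_interval, v, stim))
    family = VClampFamily(traces=traces, junction_applied=True)
    truth = ConductanceTrace(time=t, g_exc=params.g_exc_waveform.copy(),
                             g_inh=params.g_inh_waveform.copy(),
                             e_exc=params.e_exc, e_inh=params.e_inh,
                             n_potentials=len(traces))
    return family, truth


# ---------------------------------------------------------------------------
# spontaneous EPSC traces

@dataclass
class SepscSimParams:
    """Poisson trains of biexponential-decay sEPSC kernels.

    Amplitude parameters are positive magnitudes; the generated events
    are inward (negative) currents.  Defaults follow the heterozygous
    ON-SAC condition: ~14.8 events/s over 38 s with decay time
    constants tau_fast = 464 us and tau_slow = 53 ms; the rise time
    constant (200 us) makes events steep enough for derivative
    thresholding.
    """

    rate: float = 14.8                  # events/s
    amp_fast: float = 20.0              # pA
    amp_slow: float = 5.0               # pA
    tau_rise: float = 200e-6            # s
    tau_fast: float = 464e-6            # s (decay)
    tau_slow: float = 53e-3             # s (decay)
    slow_fluctuation_sd: float = 3.0    # pA
    slow_fluctuation_cutoff: float = 2.0  # Hz
    white_noise_sd: float = 0.5         # pA
    duration: float = 38.0              # s
    sampling_interval: float = 1e-4     # s
    seed: int = 0

    def __post_init__(self):
        if not self.tau_fast < self.tau_slow:
            raise ValueError("tau_fast must be < tau_slow")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


def sepsc_kernel(params: SepscSimParams,
                 n_samples: Optional[int] = None) -> np.ndarray:
    """The analytic event waveform (pA, negative-going) at t >= 0:

    -[A_f (e^{-t/tau_f} - e^{-t/tau_r}) + A_s (e^{-t/tau_s} - e^{-t/tau_r})]
    """
    if n_samples is None:
        n_samples = int(round(6 * params.tau_slow / params.sampling_interval))
    t = np.arange(n_samples) * params.sampling_interval
    rise = np.exp(-t / params.tau_rise)
    k = (params.amp_fast * (np.exp(-t / params.tau_fast) - rise)
         + params.amp_slow * (np.exp(-t / params.tau_slow) - rise))
    return -k


def _lowpass_noise(rng, n, dt, cutoff, sd):
    white = rng.normal(0.0, 1.0, size=n)
    nyq = 0.5 / dt
    if cutoff >= nyq:
        out = white
    else:
        b, a = ssignal.butter(2, cutoff / nyq)
        out = ssignal.lfilter(b, a, white)
    s = out.std()
    return out * (sd / s) if s > 0 else out


def simulate_sepsc_trace(params: SepscSimParams,
                         event_times: Optional[Sequence[float]] = None,
                         ) -> Tuple[CurrentTrace, np.ndarray]:
    """Simulate a continuous current record of spontaneous EPSCs.

    Event times are homogeneous Poisson at ``params.rate`` unless given
    explicitly; each event adds one kernel.  Slow baseline wander is
    low-pass-filtered Gaussian noise; white measurement noise is added
    on top.  Returns the trace and the ground-truth event times.
    """
    rng = np.random.default_rng(params.seed)
    dt = params.sampling_interval
    n = int(round(params.duration / dt))
    kernel = sepsc_kernel(params)
    if n < kernel.size:
        warnings.warn("record shorter than one event kernel; events will be "
                      "truncated", stacklevel=2)
    if event_times is None:
        n_events = rng.poisson(params.rate * params.duration)
        times = np.sort(rng.uniform(0.0, params.duration, size=n_events))
    else:
        times = np.sort(np.asarray(event_times, dtype=float))
    trace = np.zeros(n)
    for t0 in times:
        i = int(round(t0 / dt))
        if i >= n:
            continue
        m = min(kernel.size, n - i)
        trace[i:i + m] += kernel[:m]
    if params.slow_fluctuation_sd > 0:
        trace += _lowpass_noise(rng, n, dt, params.slow_fluctuation_cutoff,
                                params.slow_fluctuation_sd)
    if params.white_noise_sd > 0:
        trace += rng.normal(0.0, params.white_noise_sd, size=n)
    return CurrentTrace(trace, dt), times


# ---------------------------------------------------------------------------
# DSGC spike rasters

@dataclass
class DsgcSimParams:
    """Inhomogeneous-Poisson ON-OFF DSGC model.

    The firing rate during a drifting bar is baseline plus ON and OFF
    Gaussian temporal envelopes centred on the times the trailing and
    leading bar edges cross the receptive-field centre, scaled by von
    Mises direction factors exp(kappa (cos(theta - mu) - 1)), a Hill
    speed factor s/(s + s50) with exponent 1 (s50 differing for narrow
    and wide bars), and a wide-bar surround factor
    (1 - surround_weight).
    """

    preferred_direction_on: float = 90.0    # deg
    preferred_direction_off: float = 90.0   # deg
    kappa_on: float = 2.0
    kappa_off: float = 2.0
    peak_rate_on: float = 120.0             # Hz (asymptotic, before speed scaling)
    peak_rate_off: float = 120.0            # Hz
    baseline_rate: float = 1.0              # Hz
    half_max_speed_narrow: float = 1000.0   # um/s
    half_max_speed_wide: float = 500.0      # um/s
    surround_weight: float = 0.3            # in [0, 1]
    rf_sigma: float = 50.0                  # um, receptive-field extent
    travel_distance: float = 1200.0         # um, bar path centred on the RF
    n_trials: int = 3
    seed: int = 0
    wide_bar_threshold: float = 300.0       # um; wider bars engage the surround

    def __post_init__(self):
        for name in ("peak_rate_on", "peak_rate_off", "baseline_rate",
                     "kappa_on", "kappa_off"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.surround_weight <= 1:
            raise ValueError("surround_weight must be in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def drifting_bar_set(directions: Sequence[float] = tuple(range(0, 360, 30)),
                     speed: float = 1000.0, bar_width: float = 200.0,
                     bar_length: float = 1000.0,
                     contrast: str = "dark") -> List[StimulusSpec]:
    """The standard drifting-bar battery: one stimulus per direction."""
    stim_int = 30.0 if contrast == "dark" else 270.0
    return [StimulusSpec(kind="drifting_bar", direction=d, speed=speed,
                         bar_width=bar_width, bar_length=bar_length,
                         stimulus_intensity=stim_int,
                         background_intensity=150.0)
            for d in directions]


def _edge_times(params: DsgcSimParams, stim: StimulusSpec):
    """Times at which the bar's leading and trailing edges cross the RF
    centre, and which response component each edge drives."""
    s = stim.speed
    w = stim.bar_width
    t_lead = (params.travel_distance / 2.0) / s
    t_trail = (params.travel_distance / 2.0 + w) / s
    dark = weber_contrast(stim.stimulus_intensity,
                          stim.background_intensity) < 0
    if dark:
        return {"off": t_lead, "on": t_trail}   # light falls, then returns
    return {"on": t_lead, "off": t_trail}


def _rate_function(params: DsgcSimParams, stim: StimulusSpec,
                   t: np.ndarray) -> Dict[str, np.ndarray]:
    """Per-component rate contributions (Hz) on the time grid."""
    edges = _edge_times(params, stim)
    wide = stim.bar_width > params.wide_bar_threshold
    s50 = (params.half_max_speed_wide if wide
           else params.half_max_speed_narrow)
    speed_factor = stim.speed / (stim.speed + s50)
    width_factor = 1.0 - (params.surround_weight if wide else 0.0)
    sigma_t = params.rf_sigma / stim.speed
    out = {}
    for comp in ("on", "off"):
        mu = getattr(params, f"preferred_direction_{comp}")
        kappa = getattr(params, f"kappa_{comp}")
        peak = getattr(params, f"peak_rate_{comp}")
        vm = np.exp(kappa * (np.cos(np.deg2rad(stim.direction - mu)) - 1.0))
        amp = peak * vm * speed_factor * width_factor
        out[comp] = amp * np.exp(-(t - edges[comp]) ** 2 / (2 * sigma_t ** 2))
    return out


def simulate_dsgc_raster(params: DsgcSimParams,
                         stimuli: Sequence[StimulusSpec],
                         dt: float = 1e-3,
                         ) -> Tuple[List[SpikeRaster], Dict]:
    """Simulate spike rasters for a set of drifting-bar stimuli.

    Spikes are drawn per 1-ms bin from Poisson(rate * dt) and jittered
    uniformly within the bin.  Returns one raster per stimulus plus a
    ground-truth dict with the model parameters and, per stimulus, the
    analytically expected ON/OFF spikes per trial (envelope integral
    plus the baseline contribution inside each response window).
    """
    stimuli = list(stimuli)
    if not stimuli:
        raise ValueError("empty stimulus set")
    rng = np.random.default_rng(params.seed)
    rasters = []
    expected = []
    for stim in stimuli:
        if stim.kind != "drifting_bar" or stim.speed is None:
            raise ValueError("stimuli must be drifting bars with a speed")
        duration = ((params.travel_distance + stim.bar_width) / stim.speed
                    + 6 * params.rf_sigma / stim.speed)
        n_bins = int(np.ceil(duration / dt))
        t = (np.arange(n_bins) + 0.5) * dt
        comps = _rate_function(params, stim, t)
        rate = params.baseline_rate + comps["on"] + comps["off"]
        lam = np.broadcast_to(rate * dt, (params.n_trials, n_bins))
        counts = rng.poisson(lam)
        trials = []
        for k in range(params.n_trials):
            idx = np.repeat(np.arange(n_bins), counts[k])
            spikes = (idx * dt) + rng.uniform(0.0, dt, size=idx.size)
            trials.append(np.sort(spikes))
        edges = _edge_times(params, stim)
        sigma_t = params.rf_sigma / stim.speed
        windows = {c: (max(0.0, edges[c] - 3 * sigma_t),
                       edges[c] + 3 * sigma_t) for c in ("on", "off")}
        rasters.append(SpikeRaster(trials=trials, stimulus=stim,
                                   response_windows=windows))
        exp_row = {"direction": stim.direction, "speed": stim.speed,
                   "bar_width": stim.bar_width}
        # exact expected counts: baseline plus each envelope's Gaussian
        # mass inside the window (ON and OFF envelopes can overlap)
        from scipy.stats import norm
        for comp in ("on", "off"):
            w0, w1 = windows[comp]
            total = params.baseline_rate * (w1 - w0)
            for other in ("on", "off"):
                amp = comps[other].max() if comps[other].size else 0.0
                mass = (norm.cdf((w1 - edges[other]) / sigma_t)
                        - norm.cdf((w0 - edges[other]) / sigma_t))
                total += amp * sigma_t * np.sqrt(2 * np.pi) * mass
            exp_row[f"expected_{comp}_spikes"] = total
        expected.append(exp_row)
    truth = {
        "preferred_direction_on": params.preferred_direction_on,
        "preferred_direction_off": params.preferred_direction_off,
        "kappa_on": params.kappa_on, "kappa_off": params.kappa_off,
        "surround_weight": params.surround_weight,
        "half_max_speed_narrow": params.half_max_speed_narrow,
        "half_max_speed_wide": params.half_max_speed_wide,
        "expected": expected,
    }
    return rasters, truth


# ---------------------------------------------------------------------------
# IPL depth profiles

@dataclass
class ProfileSimParams:
    """Gaussian-band model of one channel's IPL depth profile.

    ``band_centers`` are depth fractions in (0, 1); a ChAT-like
    reference channel has exactly two bands.  Widths are Gaussian SDs
    in depth fraction; amplitudes are arbitrary intensity units over a
    constant baseline.
    """

    band_centers: Tuple[float, ...] = (0.28, 0.63)
    band_widths: Tuple[float, ...] = (0.04, 0.04)
    band_amplitudes: Tuple[float, ...] = (1.0, 1.0)
    ipl_thickness_px: int = 201
    baseline: float = 0.1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        c = np.asarray(self.band_centers, dtype=float)
        if c.size < 1 or np.any(np.diff(c) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if np.any((c <= 0) | (c >= 1)):
            raise ValueError("band centers must lie inside (0, 1)")
        if not (len(self.band_centers) == len(self.band_widths)
                == len(self.band_amplitudes)):
            raise ValueError("band parameter lists must have equal length")
        if self.ipl_thickness_px < 8:
            raise ValueError("ipl_thickness_px too small")


def _profile_from_params(p: ProfileSimParams, rng,
                         channel: str, group: str,
                         animal=None, image=None) -> DepthProfile:
    depth = np.linspace(0.0, 100.0, p.ipl_thickness_px)
    y = np.full(p.ipl_thickness_px, float(p.baseline))
    for c, w, a in zip(p.band_centers, p.band_widths, p.band_amplitudes):
        y += a * np.exp(-(depth - 100 * c) ** 2 / (2 * (100 * w) ** 2))
    if p.noise_sd > 0:
        y = y + rng.normal(0.0, p.noise_sd, size=y.size)
    return DepthProfile(depth=depth, intensity=y, channel=channel,
                        group=group, animal=animal, image=image)


def simulate_depth_profile(reference: ProfileSimParams,
                           target: Optional[ProfileSimParams] = None,
                           group: str = "", animal=None, image=None,
                           ) -> Tuple[DepthProfile, Optional[DepthProfile], Dict]:
    """Simulate a co-registered (reference, target) profile pair.

    The reference channel must have exactly two bands (ChAT-like).  The
    two channels share the depth axis but have independent noise drawn
    from one seeded stream.  Returns (reference_profile,
    target_profile or None, ground_truth) where the ground truth holds
    the true band centres in % depth.
    """
    if len(reference.band_centers) != 2:
        raise ValueError("reference channel needs exactly two bands")
    rng = np.random.default_rng(reference.seed)
    ref = _profile_from_params(reference, rng, channel="reference",
                               group=group, animal=animal, image=image)
    tgt = None
    if target is not None:
        if target.ipl_thickness_px != reference.ipl_thickness_px:
            raise ValueError("channels must share the depth axis")
        tgt = _profile_from_params(target, rng, channel="target",
                                   group=group, animal=animal, image=image)
    truth = {
        "reference_centers_pct": [100 * c for c in reference.band_centers],
        "reference_amplitudes": list(reference.band_amplitudes),
    }
    if target is not None:
        truth["target_centers_pct"] = [100 * c for c in target.band_centers]
        truth["target_amplitudes"] = list(target.band_amplitudes)
    return ref, tgt, truth


def profile_stack(reference: ProfileSimParams,
                  target: ProfileSimParams,
                  width_px: int = 32, n_slices: int = 5,
                  ) -> ImageStack:
    """Render the 1-D band model as a small two-channel z-stack.

    Each slice repeats the depth profile across the x axis with
    independent pixel noise; intended only to exercise the projection
    and profile-extraction path, not to emulate real micrographs.
    """
    rng = np.random.default_rng(reference.seed)
    ref, tgt, _ = simulate_depth_profile(
        ProfileSimParams(**{**reference.__dict__, "noise_sd": 0.0}),
        ProfileSimParams(**{**target.__dict__, "noise_sd": 0.0}))
    ny = ref.intensity.size
    pix = np.empty((n_slices, ny, width_px, 2))
    for z in range(n_slices):
        for ci, (prof, p) in enumerate(((ref, reference), (tgt, target))):
            plane = np.tile(prof.intensity[:, None], (1, width_px))
            if p.noise_sd > 0:
                plane = plane + rng.normal(0.0, p.noise_sd, size=plane.shape)
            pix[z, :, :, ci] = plane
    return ImageStack(pixels=pix, channel_names=("reference", "target"),
                      reference_channel="reference")
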