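"""Conductance analysis of light-evoked voltage-clamp currents.

A family of current traces recorded at several holding potentials is
decomposed into time-resolved excitatory and inhibitory synaptic
conductances.  The model is linear: at each analysis time point the net
evoked current obeys

    I_net(V, t) = g_E(t) (V - E_exc) + g_I(t) (V - E_inh)

with fixed reversal potentials (defaults E_exc = 0 mV, E_inh = -69 mV).
g_E(t) and g_I(t) are estimated by ordinary least squares across the
holding potentials, within consecutive analysis bins (default 10 ms,
raw samples averaged within each bin before fitting).  Fitted
conductances are reported unclipped — negative values flag violations
of the linear model rather than being hidden.

Units throughout: time s, voltage mV, current pA, conductance nS
(1 nS x 1 mV = 1 pA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._model import Model, Results
from . import io as _io
from .stimulus import StimulusSpec

__all__ = [
    "CurrentTrace", "VClampFamily", "IVRelation", "ConductanceTrace",
    "NetEvokedCurrents", "ConductanceModel", "ConductanceResults",
    "apply_junction_correction", "leak_iv", "net_evoked_currents",
    "decompose_conductance", "peak_conductance", "subtract_conductance",
    "write_family", "read_family", "write_conductance", "read_conductance",
]

DEFAULT_E_EXC = 0.0     # mV, excitatory (cation) reversal
DEFAULT_E_INH = -69.0   # mV, chloride reversal with this internal solution
DEFAULT_JUNCTION_MV = -10.0
DEFAULT_ANALYSIS_INTERVAL = 0.010  # s


@dataclass
class CurrentTrace:
    """One voltage-clamp current record.

    ``samples`` are in pA at fixed ``sampling_interval`` (s);
    ``holding_potential`` is the junction-corrected value in mV.
    """

    samples: np.ndarray
    sampling_interval: float
    holding_potential: float = np.nan
    stimulus: Optional[StimulusSpec] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("current samples must be finite")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sampling_interval

    @property
    def duration(self) -> float:
        return self.samples.size * self.sampling_interval


@dataclass
class VClampFamily:
    """Current traces over a set of holding potentials, one stimulus.

    ``baseline_window`` (s) is an interval preceding stimulus onset used
    for leak/baseline estimation; default is the 100 ms immediately
    before onset.
    """

    traces: List[CurrentTrace]
    junction_potential: float = DEFAULT_JUNCTION_MV
    junction_applied: bool = False
    baseline_window: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if len({t.holding_potential for t in self.traces}) < 2:
            raise ValueError("a family needs >= 2 distinct holding potentials")
        n = {t.samples.size for t in self.traces}
        dt = {t.sampling_interval for t in self.traces}
        if len(n) != 1 or len(dt) != 1:
            raise ValueError("all traces must share one time base")
        if self.baseline_window is None:
            onset = self.stimulus.onset if (self.stimulus and
                                            self.stimulus.onset is not None) else 0.1
            self.baseline_window = (max(0.0, onset - 0.1), onset)

    @property
    def stimulus(self) -> Optional[StimulusSpec]:
        return self.traces[0].stimulus

    @property
    def sampling_interval(self) -> float:
        return self.traces[0].sampling_interval

    @property
    def time(self) -> np.ndarray:
        return self.traces[0].time

    @property
    def holding_potentials(self) -> np.ndarray:
        return np.array([t.holding_potential for t in self.traces])

    @property
    def currents(self) -> np.ndarray:
        """(n_potentials, n_samples) current matrix in pA."""
        return np.stack([t.samples for t in self.traces])


@dataclass
class IVRelation:
    """A least-squares line through (V, I) points."""

    voltages: np.ndarray
    currents: np.ndarray
    slope: float          # nS
    reversal: float       # mV; NaN when the line is flat
    residual_rms: float   # pA
    degenerate: bool = False


@dataclass
class ConductanceTrace:
    """Time-resolved excitatory/inhibitory conductance estimates."""

    time: np.ndarray          # s, bin centres at the analysis interval
    g_exc: np.ndarray         # nS
    g_inh: np.ndarray         # nS
    e_exc: float = DEFAULT_E_EXC
    e_inh: float = DEFAULT_E_INH
    fit_residual_rms: Optional[np.ndarray] = None   # pA per time point
    n_potentials: int = 0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.g_exc = np.asarray(self.g_exc, dtype=float)
        self.g_inh = np.asarray(self.g_inh, dtype=float)
        if not (self.time.size == self.g_exc.size == self.g_inh.size):
            raise ValueError("time/g_exc/g_inh lengths differ")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not self.e_exc > self.e_inh:
            raise ValueError("e_exc must exceed e_inh")


# ---------------------------------------------------------------------------
# operations

def apply_junction_correction(family: VClampFamily,
                              jp: float = DEFAULT_JUNCTION_MV) -> VClampFamily:
    """Shift every holding potential by the liquid junction potential.

    The correction may be applied once; re-applying raises.
    """
    if family.junction_applied:
        raise ValueError("junction correction already applied to this family")
    traces = [replace(t, samples=t.samples.copy(),
                      holding_potential=t.holding_potential + jp)
              for t in family.traces]
    return VClampFamily(traces=traces, junction_potential=jp,
                        junction_applied=True,
                        baseline_window=family.baseline_window)


def _baseline_slice(family: VClampFamily) -> slice:
    t0, t1 = family.baseline_window
    onset = (family.stimulus.onset
             if family.stimulus and family.stimulus.onset is not None else None)
    if onset is not None and t1 > onset + 1e-12:
        raise ValueError("baseline window overlaps the stimulus")
    dt = family.sampling_interval
    i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
    if i1 <= i0:
        raise ValueError("empty baseline window")
    return slice(i0, i1)


def leak_iv(family: VClampFamily) -> IVRelation:
    """Passive (leak) current-voltage relation from the pre-stimulus baseline.

    Baseline current is the per-trace mean over ``baseline_window``; the
    returned line is the least-squares fit across holding potentials,
    with slope in nS and reversal (x-intercept) in mV.
    """
    sl = _baseline_slice(family)
    v = family.holding_potentials
    i = family.currents[:, sl].mean(axis=1)
    slope, intercept = np.polyfit(v, i, 1)
    resid = i - (slope * v + intercept)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    if abs(slope) < 1e-12:
        return IVRelation(v, i, 0.0, np.nan, rms, degenerate=True)
    return IVRelation(v, i, float(slope), float(-intercept / slope), rms)


@dataclass
class NetEvokedCurrents:
    """Baseline-subtracted evoked currents per holding potential."""

    time: np.ndarray                  # s
    voltages: np.ndarray              # mV
    currents: np.ndarray              # (n_potentials, n_samples) pA
    sampling_interval: float
    stimulus: Optional[StimulusSpec] = None


def net_evoked_currents(family: VClampFamily) -> NetEvokedCurrents:
    """Subtract each trace's own baseline mean (a per-trace scalar).

    For a stationary leak this removes leak plus offset at every
    potential, leaving the net light-evoked current.
    """
    sl = _baseline_slice(family)
    cur = family.currents
    net = cur - cur[:, sl].mean(axis=1, keepdims=True)
    return NetEvokedCurrents(time=family.time,
                             voltages=family.holding_potentials,
                             currents=net,
                             sampling_interval=family.sampling_interval,
                             stimulus=family.stimulus)


class ConductanceModel(Model):
    """Least-squares decomposition of net currents into g_E(t), g_I(t).

    Parameters
    ----------
    net : NetEvokedCurrents
        Baseline-subtracted currents over >= 2 holding potentials.
    e_exc, e_inh : float
        Fixed reversal potentials in mV (must differ).
    interval : float
        Analysis bin width in seconds; raw samples are averaged within
        each bin before the per-bin linear solve.
    """

    def __init__(self, net: NetEvokedCurrents,
                 e_exc: float = DEFAULT_E_EXC,
                 e_inh: float = DEFAULT_E_INH,
                 interval: float = DEFAULT_ANALYSIS_INTERVAL):
        if net.voltages.size < 2:
            raise ValueError("need >= 2 holding potentials")
        if e_exc == e_inh:
            raise ValueError("e_exc == e_inh gives a singular design")
        if interval <= 0:
            raise ValueError("analysis interval must be > 0")
        self.net = net
        self.e_exc = float(e_exc)
        self.e_inh = float(e_inh)
        self.interval = float(interval)

    def fit(self) -> "ConductanceResults":
        net = self.net
        dt = net.sampling_interval
        per_bin = max(1, int(round(self.interval / dt)))
        n_bins = net.currents.shape[1] // per_bin
        if n_bins == 0:
            raise ValueError("trace shorter than one analysis bin")
        trimmed = net.currents[:, :n_bins * per_bin]
        # average raw samples within each analysis bin, per potential
        binned = trimmed.reshape(net.voltages.size, n_bins, per_bin).mean(axis=2)
        t = (np.arange(n_bins) + 0.5) * per_bin * dt

        v = net.voltages
        design = np.column_stack([v - self.e_exc, v - self.e_inh])
        # one least-squares solve for all bins at once
        sol, *_ = np.linalg.lstsq(design, binned, rcond=None)
        g_exc, g_inh = sol
        resid = binned - design @ sol
        rms = np.sqrt(np.mean(resid ** 2, axis=0))

        trace = ConductanceTrace(time=t, g_exc=g_exc, g_inh=g_inh,
                                 e_exc=self.e_exc, e_inh=self.e_inh,
                                 fit_residual_rms=rms,
                                 n_potentials=int(v.size))
        return ConductanceResults(self, trace)


class ConductanceResults(Results):
    """Fitted conductance trace plus scalar diagnostics."""

    def __init__(self, model: ConductanceModel, trace: ConductanceTrace):
        self.conductance = trace
        params = {
            "peak_g_exc_nS": float(np.max(trace.g_exc)),
            "peak_g_inh_nS": float(np.max(trace.g_inh)),
        }
        diagnostics = {
            "mean_residual_rms_pA": float(np.mean(trace.fit_residual_rms)),
            "n_potentials": trace.n_potentials,
            "n_bins": int(trace.time.size),
            "e_exc_mV": trace.e_exc,
            "e_inh_mV": trace.e_inh,
        }
        super().__init__(model, params, diagnostics=diagnostics)


def decompose_conductance(net: NetEvokedCurrents,
                          e_exc: float = DEFAULT_E_EXC,
                          e_inh: float = DEFAULT_E_INH,
                          interval: float = DEFAULT_ANALYSIS_INTERVAL,
                          ) -> ConductanceTrace:
    """Convenience wrapper: fit the linear conductance model, return the trace."""
    return ConductanceModel(net, e_exc, e_inh, interval).fit().conductance


def peak_conductance(trace: ConductanceTrace,
                     window: Optional[Tuple[float, float]] = None,
                     ) -> dict:
    """Peak of each conductance component within a response window.

    ``window`` defaults to the whole trace.  Returns
    ``{"exc": (value_nS, time_s), "inh": (value_nS, time_s)}``; ties are
    broken to the earliest time.
    """
    if window is None:
        window = (trace.time[0], trace.time[-1])
    t0, t1 = window
    mask = (trace.time >= t0 - 1e-12) & (trace.time <= t1 + 1e-12)
    if not mask.any():
        raise ValueError("empty peak-search window")
    t = trace.time[mask]
    out = {}
    for name, g in (("exc", trace.g_exc[mask]), ("inh", trace.g_inh[mask])):
        i = int(np.argmax(g))          # argmax returns the first maximum
        out[name] = (float(g[i]), float(t[i]))
    return out


def default_peak_window(stimulus: StimulusSpec) -> Tuple[float, float]:
    """Default peak search window: stimulus onset to offset + 200 ms."""
    if stimulus.onset is None or stimulus.offset is None:
        raise ValueError("stimulus onset/offset required")
    return (stimulus.onset, stimulus.offset + 0.2)


def subtract_conductance(a: ConductanceTrace, b: ConductanceTrace,
                         ) -> ConductanceTrace:
    """Pointwise a - b per component (genotype or drug subtraction).

    Requires identical time bases and reversal potentials; no
    resampling is attempted.
    """
    if a.time.size != b.time.size or not np.allclose(a.time, b.time):
        raise ValueError("conductance traces are on different time bases")
    if (a.e_exc, a.e_inh) != (b.e_exc, b.e_inh):
        raise ValueError("reversal potentials differ")
    return ConductanceTrace(time=a.time.copy(),
                            g_exc=a.g_exc - b.g_exc,
                            g_inh=a.g_inh - b.g_inh,
                            e_exc=a.e_exc, e_inh=a.e_inh,
                            n_potentials=min(a.n_potentials, b.n_potentials))


# ---------------------------------------------------------------------------
# file formats

def write_family(path, family: VClampFamily) -> None:
    """Wide table: one time column plus one current column per potential."""
    data = {"time_s": family.time}
    for tr in family.traces:
        data[f"i_pA_at_{tr.holding_potential:g}mV"] = tr.samples
    meta = {
        "format": "vclamp_family",
        "sampling_interval_s": family.sampling_interval,
        "junction_potential_mV": family.junction_potential,
        "junction_applied": family.junction_applied,
        "baseline_window_s": f"{family.baseline_window[0]},{family.baseline_window[1]}",
        **_io.meta_from_stimulus(family.stimulus),
    }
    _io.write_table(path, pd.DataFrame(data), meta)


def read_family(path) -> VClampFamily:
    df, meta = _io.read_table(path)
    stim = _io.stimulus_from_meta(meta)
    dt = float(meta["sampling_interval_s"])
    bw = tuple(float(x) for x in str(meta["baseline_window_s"]).split(","))
    traces = []
    for col in df.columns:
        if col.startswith("i_pA_at_"):
            v = float(col[len("i_pA_at_"):-2])
            traces.append(CurrentTrace(df[col].to_numpy(), dt, v, stim))
    return VClampFamily(traces=traces,
                        junction_potential=float(meta["junction_potential_mV"]),
                        junction_applied=bool(meta["junction_applied"]),
                        baseline_window=bw)


def write_conductance(path, trace: ConductanceTrace) -> None:
    rms = (trace.fit_residual_rms if trace.fit_residual_rms is not None
           else np.full_like(trace.time, np.nan))
    df = pd.DataFrame({
        "time_s": trace.time, "g_exc_nS": trace.g_exc, "g_inh_nS": trace.g_inh,
        "residual_rms_pA": rms,
        "n_potentials": np.full(trace.time.size, trace.n_potentials, dtype=int),
    })
    _io.write_table(path, df, {"format": "conductance_trace",
                               "e_exc_mV": trace.e_exc, "e_inh_mV": trace.e_inh})


def read_conductance(path) -> ConductanceTrace:
    df, meta = _io.read_table(path)
    return ConductanceTrace(time=df["time_s"].to_numpy(),
                            g_exc=df["g_exc_nS"].to_numpy(),
                            g_inh=df["g_inh_nS"].to_numpy(),
                            e_exc=float(meta["e_exc_mV"]),
                            e_inh=float(meta["e_inh_mV"]),
                            fit_residual_rms=df["residual_rms_pA"].to_numpy(),
                            n_potentials=int(df["n_potentials"].iloc[0]))
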