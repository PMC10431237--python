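"""Spontaneous EPSC detection, averaging and decay kinetics.

Continuous voltage-clamp records from amacrine cells show rapid inward
sEPSCs riding on slow fluctuations of the membrane current.
Differentiating the record suppresses the slow fluctuations and
emphasises the fast events; events are detected where the derivative
crosses a threshold set at a multiple (default 5) of the derivative
noise SD.  Segments around each event are excised, baseline-subtracted
and averaged, and the decay phase of the average event is fitted with a
double exponential A_f exp(-t/tau_f) + A_s exp(-t/tau_s).

The derivative-threshold detector intrinsically favours fast, large
events; no correction for this selection bias is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import lmfit

from ._model import Model, Results, minimize_quietly
from .vclamp import CurrentTrace

__all__ = [
    "EventCatalog", "AverageEvent", "DecayFit",
    "detect_events", "average_events", "event_frequency", "group_frequency",
    "DecayModel", "DecayResults", "fit_decay",
]

DEFAULT_THRESHOLD_MULTIPLE = 5.0
DEFAULT_MIN_SEPARATION = 0.005          # s
DEFAULT_EXCISION_WINDOW = (0.010, 0.250)  # (pre, post) s
_MAD_TO_SD = 1.4826                     # consistency factor for Gaussian noise


@dataclass
class EventCatalog:
    """Detected event times with their detection context."""

    event_times: np.ndarray       # s, strictly increasing
    threshold: float              # pA/s
    noise_sd_derivative: float    # pA/s
    threshold_multiple: float
    min_separation: float         # s
    source_duration: float        # s
    polarity: str = "inward"

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.event_times.size > 1:
            gaps = np.diff(self.event_times)
            if not np.all(gaps > 0):
                raise ValueError("event times must be strictly increasing")
            if np.any(gaps < self.min_separation - 1e-12):
                raise ValueError("events closer than min_separation")

    def __len__(self):
        return self.event_times.size


@dataclass
class AverageEvent:
    """Baseline-subtracted mean of excised event segments."""

    time: np.ndarray         # s relative to the alignment point
    mean_current: np.ndarray  # pA
    n_events: int
    excision_window: Tuple[float, float]
    n_dropped: int = 0
    sampling_interval: float = 0.0


@dataclass
class DecayFit:
    """Double-exponential decay parameters of an average event."""

    amp_fast: float    # pA (signed; negative for inward events)
    tau_fast: float    # s
    amp_slow: float    # pA
    tau_slow: float    # s
    fit_start: float   # s, time of the event extremum
    rms: float         # pA
    degenerate: bool = False


def detect_events(trace: CurrentTrace,
                  threshold_multiple: float = DEFAULT_THRESHOLD_MULTIPLE,
                  min_separation: float = DEFAULT_MIN_SEPARATION,
                  polarity: str = "inward") -> EventCatalog:
    """Threshold the derivative of a current record at a multiple of its noise SD.

    The derivative is computed by first differences divided by the
    sampling interval.  Its noise SD is estimated robustly as the scaled
    median absolute deviation over the whole record (robust to the
    events themselves).  Crossings in the event-going direction
    (negative derivative for inward EPSCs) are collapsed so that
    crossings within ``min_separation`` of an accepted event are
    ignored; the event time is the first crossing sample.
    """
    if polarity not in ("inward", "outward"):
        raise ValueError("polarity must be 'inward' or 'outward'")
    dt = trace.sampling_interval
    deriv = np.diff(trace.samples) / dt
    if polarity == "outward":
        deriv = -deriv
    mad = np.median(np.abs(deriv - np.median(deriv)))
    noise_sd = _MAD_TO_SD * mad
    if noise_sd <= 0:
        raise ValueError(
            "derivative noise SD is zero (constant trace?); "
            "supply a record with measurable baseline noise")
    threshold = threshold_multiple * noise_sd

    below = deriv < -threshold          # inward-going crossings
    # crossing starts: first sample of each below-threshold run
    starts = np.flatnonzero(below & ~np.concatenate(([False], below[:-1])))
    times = []
    last = -np.inf
    for i in starts:
        t = (i + 1) * dt                # sample where the step is visible
        if t - last >= min_separation:
            times.append(t)
            last = t
    return EventCatalog(event_times=np.array(times),
                        threshold=threshold,
                        noise_sd_derivative=noise_sd,
                        threshold_multiple=threshold_multiple,
                        min_separation=min_separation,
                        source_duration=trace.duration,
                        polarity=polarity)


def average_events(trace: CurrentTrace, catalog: EventCatalog,
                   window: Tuple[float, float] = DEFAULT_EXCISION_WINDOW,
                   ) -> AverageEvent:
    """Excise a (pre, post) window around each event and average.

    Each segment's local baseline (its mean over the pre-window) is
    subtracted before averaging; events whose window would run off the
    record are dropped and counted in ``n_dropped``.
    """
    if len(catalog) == 0:
        raise ValueError("cannot average an empty event catalog")
    pre, post = window
    if pre < 0 or post <= 0:
        raise ValueError("window must be (pre >= 0, post > 0) in seconds")
    dt = trace.sampling_interval
    n_pre = int(round(pre / dt))
    n_post = int(round(post / dt))
    n = trace.samples.size
    segments = []
    dropped = 0
    for t in catalog.event_times:
        i = int(round(t / dt))
        if i - n_pre < 0 or i + n_post > n:
            dropped += 1
            continue
        seg = trace.samples[i - n_pre:i + n_post].astype(float)
        if n_pre > 0:
            seg = seg - seg[:n_pre].mean()
        segments.append(seg)
    if not segments:
        raise ValueError("no event window fits inside the record")
    mean = np.mean(segments, axis=0)
    time = (np.arange(-n_pre, n_post)) * dt
    return AverageEvent(time=time, mean_current=mean,
                        n_events=len(segments),
                        excision_window=(pre, post),
                        n_dropped=dropped,
                        sampling_interval=dt)


def event_frequency(catalog: EventCatalog) -> float:
    """Event rate: count / source duration (events/s)."""
    if catalog.source_duration <= 0:
        raise ValueError("source_duration must be > 0")
    return len(catalog) / catalog.source_duration


def group_frequency(catalogs: Sequence[EventCatalog],
                    method: str = "pooled") -> float:
    """Frequency across several cells' catalogs.

    ``pooled`` (default): total events / total duration.
    ``per_cell``: mean of each cell's own rate.
    """
    if method == "pooled":
        total = sum(len(c) for c in catalogs)
        dur = sum(c.source_duration for c in catalogs)
        if dur <= 0:
            raise ValueError("total duration must be > 0")
        return total / dur
    if method == "per_cell":
        return float(np.mean([event_frequency(c) for c in catalogs]))
    raise ValueError("method must be 'pooled' or 'per_cell'")


def _biexp(t, amp_fast, tau_fast, amp_slow, tau_slow):
    return amp_fast * np.exp(-t / tau_fast) + amp_slow * np.exp(-t / tau_slow)


class DecayModel(Model):
    """Double-exponential fit to the decay phase of an average event.

    The fit starts at the extremum of the average (the pre-peak slow
    rise is excluded) and runs to the end of the excision window.
    Multi-start nonlinear least squares; components are ordered so
    tau_fast < tau_slow.  Near-equal time constants or a vanishing
    component amplitude flag the fit as degenerate (effectively a
    single exponential).
    """

    #: (tau_fast, tau_slow) starting points in seconds
    STARTS = ((5e-4, 2e-2), (3e-4, 6e-2), (1e-3, 4e-2), (2e-3, 1e-1))

    def __init__(self, avg: AverageEvent, polarity: str = "inward"):
        self.avg = avg
        self.polarity = polarity

    def fit(self) -> "DecayResults":
        avg = self.avg
        y = np.asarray(avg.mean_current, dtype=float)
        if self.polarity == "inward":
            i_peak = int(np.argmin(y))
        else:
            i_peak = int(np.argmax(y))
        if i_peak >= y.size - 4:
            raise ValueError("no decay phase after the event extremum")
        t0 = avg.time[i_peak]
        t = avg.time[i_peak:] - t0
        yd = y[i_peak:]
        peak = yd[0]

        best = None
        for tf0, ts0 in self.STARTS:
            p = lmfit.Parameters()
            # amplitudes share the sign of the peak
            p.add("amp_fast", value=0.7 * peak)
            p.add("amp_slow", value=0.3 * peak)
            p.add("tau_fast", value=tf0, min=avg.sampling_interval / 4, max=1.0)
            p.add("tau_slow", value=ts0, min=avg.sampling_interval / 4, max=10.0)
            try:
                res = minimize_quietly(
                    lambda pp: _biexp(t, pp["amp_fast"], pp["tau_fast"],
                                      pp["amp_slow"], pp["tau_slow"]) - yd,
                    p, method="least_squares")
            except Exception:
                continue
            rms = float(np.sqrt(np.mean(res.residual ** 2)))
            if best is None or rms < best[0]:
                best = (rms, res)
        if best is None:
            raise RuntimeError("decay fit failed to converge from any start")
        rms, res = best

        v = {k: float(res.params[k].value) for k in res.params}
        e = {k: (float(res.params[k].stderr)
                 if res.params[k].stderr is not None else np.nan)
             for k in res.params}
        if v["tau_fast"] > v["tau_slow"]:   # order components
            v["tau_fast"], v["tau_slow"] = v["tau_slow"], v["tau_fast"]
            v["amp_fast"], v["amp_slow"] = v["amp_slow"], v["amp_fast"]
            e["tau_fast"], e["tau_slow"] = e["tau_slow"], e["tau_fast"]
            e["amp_fast"], e["amp_slow"] = e["amp_slow"], e["amp_fast"]
        amp_scale = max(abs(v["amp_fast"]), abs(v["amp_slow"]), abs(peak))
        degenerate = (v["tau_slow"] < 1.5 * v["tau_fast"]
                      or abs(v["amp_fast"]) < 0.01 * amp_scale
                      or abs(v["amp_slow"]) < 0.01 * amp_scale)
        fit = DecayFit(amp_fast=v["amp_fast"], tau_fast=v["tau_fast"],
                       amp_slow=v["amp_slow"], tau_slow=v["tau_slow"],
                       fit_start=float(t0), rms=rms, degenerate=degenerate)
        return DecayResults(self, fit, e)


class DecayResults(Results):
    def __init__(self, model: DecayModel, fit: DecayFit, bse: dict):
        self.decay = fit
        params = {"amp_fast_pA": fit.amp_fast, "tau_fast_s": fit.tau_fast,
                  "amp_slow_pA": fit.amp_slow, "tau_slow_s": fit.tau_slow}
        bse_named = {"amp_fast_pA": bse.get("amp_fast", np.nan),
                     "tau_fast_s": bse.get("tau_fast", np.nan),
                     "amp_slow_pA": bse.get("amp_slow", np.nan),
                     "tau_slow_s": bse.get("tau_slow", np.nan)}
        diagnostics = {"rms_pA": fit.rms, "fit_start_s": fit.fit_start,
                       "degenerate": fit.degenerate,
                       "n_events": model.avg.n_events}
        super().__init__(model, params, bse_named, diagnostics)

    def predict(self, t: np.ndarray) -> np.ndarray:
        f = self.decay
        return _biexp(np.asarray(t, float), f.amp_fast, f.tau_fast,
                      f.amp_slow, f.tau_slow)


def fit_decay(avg: AverageEvent, polarity: str = "inward") -> DecayFit:
    """Fit the average event's decay; returns the DecayFit record."""
    return DecayModel(avg, polarity=polarity).fit().decay
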