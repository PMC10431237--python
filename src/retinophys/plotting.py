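"""Figure helpers mirroring the standard presentation of each stage:
conductance traces with difference overlays, average events with decay
fits, polar tuning plots, and depth profiles with band shading."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .events import AverageEvent, DecayFit
from .ihc import CHAT_ANCHORS, DepthProfile
from .tuning import TuningCurve
from .vclamp import ConductanceTrace

__all__ = ["plot_conductance", "plot_average_event", "plot_tuning_polar",
           "plot_depth_profiles"]


def _ax(ax, polar=False):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(subplot_kw={"polar": True} if polar else None)
    return ax


def plot_conductance(trace: ConductanceTrace, ax=None,
                     difference: Optional[ConductanceTrace] = None):
    """Excitatory/inhibitory conductance vs time; an optional
    difference trace (e.g. control minus drug) is overlaid."""
    ax = _ax(ax)
    ax.plot(trace.time, trace.g_exc, color="k", label="g_exc")
    ax.plot(trace.time, trace.g_inh, color="0.5", label="g_inh")
    if difference is not None:
        ax.plot(difference.time, difference.g_exc, color="m", lw=1,
                label="difference g_exc")
        ax.plot(difference.time, difference.g_inh, color="c", lw=1,
                label="difference g_inh")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("conductance (nS)")
    ax.legend(frameon=False, fontsize="small")
    return ax


def plot_average_event(avg: AverageEvent, fit: Optional[DecayFit] = None,
                       ax=None):
    """The average sEPSC, with the biexponential decay fit overlaid."""
    ax = _ax(ax)
    ax.plot(avg.time * 1e3, avg.mean_current, color="k",
            label=f"average of {avg.n_events} events")
    if fit is not None:
        t = avg.time[avg.time >= fit.fit_start] - fit.fit_start
        y = (fit.amp_fast * np.exp(-t / fit.tau_fast)
             + fit.amp_slow * np.exp(-t / fit.tau_slow))
        ax.plot((t + fit.fit_start) * 1e3, y, color="r", lw=1,
                label=(f"decay fit: tau_f = {fit.tau_fast*1e6:.0f} us, "
                       f"tau_s = {fit.tau_slow*1e3:.1f} ms"))
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("current (pA)")
    ax.legend(frameon=False, fontsize="small")
    return ax


def plot_tuning_polar(curve: TuningCurve, fit=None, ax=None):
    """Polar tuning plot; the von Mises fit is drawn as a smooth line."""
    ax = _ax(ax, polar=True)
    th = np.deg2rad(np.concatenate([curve.angles, curve.angles[:1]]))
    r = np.concatenate([curve.responses, curve.responses[:1]])
    ax.plot(th, r, "o-", color="k", ms=4)
    if fit is not None:
        dense = np.linspace(0, 360, 361)
        ax.plot(np.deg2rad(dense), fit.predict(dense), color="r", lw=1)
    if np.isfinite(curve.preferred_direction):
        ax.annotate(f"DSI(vec) = {curve.vector_dsi:.2f}",
                    xy=(0.02, 0.98), xycoords="axes fraction", va="top",
                    fontsize="small")
    return ax


def plot_depth_profiles(profiles: Sequence[DepthProfile], ax=None,
                        shade_bands: bool = True,
                        difference: Optional[DepthProfile] = None):
    """Aligned depth profiles (mean +/- SEM) with the fiducial bands
    shaded; an optional group difference profile is overlaid."""
    ax = _ax(ax)
    for prof in profiles:
        line, = ax.plot(prof.depth, prof.intensity,
                        label=prof.group or prof.channel)
        if prof.sem is not None:
            ax.fill_between(prof.depth, prof.intensity - prof.sem,
                            prof.intensity + prof.sem,
                            color=line.get_color(), alpha=0.25, lw=0)
    if difference is not None:
        ax.plot(difference.depth, difference.intensity, color="c", lw=1,
                label=difference.group or "difference")
    if shade_bands:
        for anchor in CHAT_ANCHORS:
            ax.axvspan(anchor - 2, anchor + 2, color="pink", alpha=0.4, lw=0)
    ax.set_xlabel("IPL depth (%)")
    ax.set_ylabel("normalized intensity")
    ax.legend(frameon=False, fontsize="small")
    return ax
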