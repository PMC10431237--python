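"""Spike-train analyses for direction-selective ganglion cells.

Drifting-bar responses are summarised as peristimulus time histograms
(PSTHs) pooled over trials; ON (trailing-edge) and OFF (leading-edge)
responses are integrated or peak-measured within response windows.

Directional tuning over 12 directions (30 deg spacing by convention,
any grid accepted) is quantified two ways, both reported explicitly:

* ``vector_dsi`` — the normalised length of the vector sum of the
  responses, |sum r_k e^{i theta_k}| / sum r_k, in [0, 1]; the
  preferred direction is the angle of the resultant.
* ``prefnull_dsi`` — (R_pref - R_null) / (R_pref + R_null), with the
  null response taken at the measured angle nearest to 180 deg from
  the preferred.

Tuning curves are fitted with a peak-normalised von Mises function
R(theta) = baseline + amplitude exp(kappa (cos(theta - mu) - 1)).
Area-response (spot-diameter) data are fitted with a disc-integrated
difference-of-Gaussians; speed tuning with a Hill function with the
exponent fixed at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import lmfit

from ._model import Model, Results, minimize_quietly
from .stimulus import StimulusSpec, normalize_direction

__all__ = [
    "SpikeRaster", "PSTH", "TuningCurve", "AreaResponse", "SpeedTuning",
    "build_psth", "integrate_response", "peak_rate",
    "vector_sum", "dsi_pref_null", "pref_null_responses",
    "onoff_misalignment",
    "VonMisesModel", "VonMisesResults", "fit_von_mises",
    "AreaResponseModel", "AreaResponseResults", "fit_area_response",
    "SpeedTuningModel", "SpeedTuningResults", "fit_speed_tuning",
]


@dataclass
class SpikeRaster:
    """Spike times for repeated presentations of one stimulus."""

    trials: list                         # list of arrays of spike times (s)
    stimulus: Optional[StimulusSpec] = None
    response_windows: Optional[Dict[str, Tuple[float, float]]] = None

    def __post_init__(self):
        clean = []
        for tr in self.trials:
            a = np.asarray(tr, dtype=float)
            if a.size and (np.any(a < 0) or np.any(np.diff(a) < 0)):
                raise ValueError("spike times must be nonnegative and sorted")
            clean.append(a)
        self.trials = clean

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class PSTH:
    """Trial-pooled spike rate versus time."""

    bin_edges: np.ndarray   # s
    rate: np.ndarray        # Hz = spikes per bin / (n_trials * bin_width)
    n_trials: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.rate.size != self.bin_edges.size - 1:
            raise ValueError("rate length must be len(bin_edges) - 1")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def build_psth(raster: SpikeRaster, bin_width: float = 0.025,
               t_stop: Optional[float] = None) -> PSTH:
    """Accumulate spikes over trials into a rate histogram.

    Rate in each bin is (pooled count) / (n_trials * bin_width), in Hz.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if raster.n_trials < 1:
        raise ValueError("need at least one trial")
    if t_stop is None:
        last = max((tr[-1] for tr in raster.trials if tr.size), default=0.0)
        if raster.stimulus is not None and raster.stimulus.offset is not None:
            last = max(last, raster.stimulus.offset)
        t_stop = last + bin_width
    n_bins = max(1, int(np.ceil(t_stop / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    pooled = np.concatenate([tr for tr in raster.trials]) if raster.trials else np.array([])
    counts, _ = np.histogram(pooled, bins=edges)
    rate = counts / (raster.n_trials * bin_width)
    return PSTH(bin_edges=edges, rate=rate, n_trials=raster.n_trials)


def _window_mask(psth: PSTH, window: Tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    centers = psth.bin_centers
    mask = (centers >= t0) & (centers < t1)
    if not mask.any():
        raise ValueError("window contains no PSTH bins")
    return mask


def integrate_response(psth: PSTH, window: Tuple[float, float]) -> float:
    """Integral of rate over the window: average spikes per trial."""
    mask = _window_mask(psth, window)
    return float(np.sum(psth.rate[mask]) * psth.bin_width)


def peak_rate(psth: PSTH, window: Tuple[float, float]) -> Tuple[float, float]:
    """Maximum bin rate in the window and the time of that bin."""
    mask = _window_mask(psth, window)
    rates = psth.rate[mask]
    centers = psth.bin_centers[mask]
    i = int(np.argmax(rates))
    return float(rates[i]), float(centers[i])


# ---------------------------------------------------------------------------
# direction selectivity

def vector_sum(angles_deg: Sequence[float], responses: Sequence[float],
               ) -> Tuple[float, float]:
    """Resultant of per-direction responses.

    Returns ``(preferred_direction_deg, vector_dsi)``.  The preferred
    direction is the angle of the resultant vector sum r_k e^{i
    theta_k}; vector_dsi is its length normalised by sum r_k, in
    [0, 1].  All-zero responses leave the direction undefined (NaN)
    with vector_dsi 0.
    """
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    r = np.asarray(responses, dtype=float)
    if th.size != r.size or th.size < 2:
        raise ValueError("need >= 2 (angle, response) pairs")
    if np.any(r < 0):
        raise ValueError("responses must be >= 0")
    total = r.sum()
    if total == 0:
        return (np.nan, 0.0)
    x = np.sum(r * np.cos(th))
    y = np.sum(r * np.sin(th))
    dsi = float(np.hypot(x, y) / total)
    pref = normalize_direction(np.rad2deg(np.arctan2(y, x)))
    return (pref, min(dsi, 1.0))


def dsi_pref_null(r_pref: float, r_null: float) -> float:
    """(R_pref - R_null) / (R_pref + R_null), in [-1, 1]."""
    if r_pref < 0 or r_null < 0:
        raise ValueError("responses must be >= 0")
    if r_pref + r_null == 0:
        return np.nan
    return (r_pref - r_null) / (r_pref + r_null)


def pref_null_responses(angles_deg: Sequence[float],
                        responses: Sequence[float],
                        preferred: Optional[float] = None,
                        ) -> Tuple[float, float]:
    """Responses at the measured angles nearest the preferred direction
    and its opposite (on a 30-deg grid both are exact)."""
    ang = np.asarray(angles_deg, dtype=float)
    r = np.asarray(responses, dtype=float)
    if preferred is None:
        preferred, _ = vector_sum(ang, r)
    if not np.isfinite(preferred):
        return (np.nan, np.nan)

    def nearest(target):
        d = np.abs((ang - target + 180.0) % 360.0 - 180.0)
        return int(np.argmin(d))

    return float(r[nearest(preferred)]), float(r[nearest(preferred + 180.0)])


def onoff_misalignment(pref_on: float, pref_off: float) -> float:
    """Smallest absolute circular difference between two directions, [0, 180]."""
    if not (np.isfinite(pref_on) and np.isfinite(pref_off)):
        return np.nan
    d = abs((pref_on - pref_off + 180.0) % 360.0 - 180.0)
    return float(d)


# ---------------------------------------------------------------------------
# von Mises tuning fit

def _von_mises(theta_deg, amplitude, mu_deg, kappa, baseline):
    d = np.deg2rad(theta_deg - mu_deg)
    return baseline + amplitude * np.exp(kappa * (np.cos(d) - 1.0))


class VonMisesModel(Model):
    """Least-squares fit of a peak-normalised von Mises tuning function.

    R(theta) = baseline + amplitude exp(kappa (cos(theta - mu) - 1));
    ``amplitude`` is the peak above baseline at theta = mu.
    """

    def __init__(self, angles_deg: Sequence[float],
                 responses: Sequence[float]):
        self.angles = np.asarray(angles_deg, dtype=float)
        self.responses = np.asarray(responses, dtype=float)
        if np.count_nonzero(self.responses) < 4:
            raise ValueError("need >= 4 angles with nonzero response")

    def fit(self) -> "VonMisesResults":
        ang, r = self.angles, self.responses
        p = lmfit.Parameters()
        p.add("amplitude", value=max(r.max() - r.min(), 1e-9), min=0.0)
        p.add("mu_deg", value=float(ang[np.argmax(r)]), min=-360, max=720)
        p.add("kappa", value=2.0, min=0.0, max=500.0)
        p.add("baseline", value=float(r.min()))
        res = minimize_quietly(
            lambda pp: _von_mises(ang, pp["amplitude"], pp["mu_deg"],
                                  pp["kappa"], pp["baseline"]) - r,
            p, method="least_squares")
        if not res.success:
            raise RuntimeError("von Mises fit did not converge; best attempt: "
                               + str({k: res.params[k].value for k in res.params}))
        v = {k: float(res.params[k].value) for k in res.params}
        e = {k: (float(res.params[k].stderr)
                 if res.params[k].stderr is not None else np.nan)
             for k in res.params}
        v["mu_deg"] = normalize_direction(v["mu_deg"])
        rms = float(np.sqrt(np.mean(res.residual ** 2)))
        scale = max(r.max() - r.min(), 0.05 * np.abs(r).max(), 1e-12)
        untuned = v["kappa"] < 0.1 or v["amplitude"] < 0.05 * scale
        return VonMisesResults(self, v, e,
                               {"rms": rms, "untuned": untuned,
                                "n_angles": int(ang.size)})


class VonMisesResults(Results):
    def predict(self, theta_deg):
        p = self.params
        return _von_mises(np.asarray(theta_deg, float), p["amplitude"],
                          p["mu_deg"], p["kappa"], p["baseline"])


def fit_von_mises(angles_deg, responses) -> VonMisesResults:
    return VonMisesModel(angles_deg, responses).fit()


@dataclass
class TuningCurve:
    """Direction-indexed responses with derived tuning statistics.

    Construct with per-angle responses (spikes/trial or peak Hz); the
    vector statistics are computed eagerly, the von Mises fit lazily
    via :meth:`fit`.
    """

    angles: np.ndarray
    responses: np.ndarray
    response_measure: str = "spikes_per_trial"
    preferred_direction: float = field(init=False)
    vector_dsi: float = field(init=False)
    prefnull_dsi: float = field(init=False)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        self.preferred_direction, self.vector_dsi = vector_sum(
            self.angles, self.responses)
        rp, rn = pref_null_responses(self.angles, self.responses,
                                     self.preferred_direction)
        self.prefnull_dsi = (dsi_pref_null(rp, rn)
                             if np.isfinite(rp) else np.nan)

    def fit(self) -> VonMisesResults:
        return fit_von_mises(self.angles, self.responses)


# ---------------------------------------------------------------------------
# area-response (difference-of-Gaussians) fit

def _dog_area(d, center_amp, center_sigma, surround_amp, surround_sigma):
    # disc-integrated concentric Gaussians: response to a filled spot of
    # diameter d centred on the receptive field
    return (center_amp * (1.0 - np.exp(-d ** 2 / (2.0 * center_sigma ** 2)))
            - surround_amp * (1.0 - np.exp(-d ** 2 / (2.0 * surround_sigma ** 2))))


@dataclass
class AreaResponse:
    """Response amplitude versus stimulus spot diameter."""

    diameters: np.ndarray   # um, strictly increasing
    responses: np.ndarray   # response magnitude (pA or Hz), >= 0

    def __post_init__(self):
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.diameters.size != self.responses.size:
            raise ValueError("diameters and responses differ in length")
        if np.any(np.diff(self.diameters) <= 0):
            raise ValueError("diameters must be strictly increasing")


def surround_suppression_percent(data: AreaResponse) -> float:
    """100 (R_opt - R_largest) / R_opt from the measured points.

    R_opt is the maximum measured response over diameters, R_largest
    the response at the largest diameter.  Computed on the data so it
    is defined even when the DoG fit is poor.
    """
    r_opt = float(np.max(data.responses))
    if r_opt <= 0:
        raise ValueError("no positive response; suppression undefined")
    r_largest = float(data.responses[-1])
    return 100.0 * (r_opt - r_largest) / r_opt


class AreaResponseModel(Model):
    """Disc-integrated difference-of-Gaussians fit to area-response data."""

    def __init__(self, data: AreaResponse):
        if data.diameters.size < 5:
            raise ValueError("need >= 5 diameters for a 4-parameter DoG fit")
        self.data = data

    def fit(self) -> "AreaResponseResults":
        d, r = self.data.diameters, self.data.responses
        rmax = max(r.max(), 1e-9)
        d_peak = d[np.argmax(r)]
        best = None
        for sc0, ss_ratio in ((d_peak / 2, 4.0), (d_peak / 3, 8.0),
                              (d_peak, 3.0)):
            p = lmfit.Parameters()
            p.add("center_amp", value=1.5 * rmax, min=0.0)
            p.add("center_sigma", value=max(sc0, 1.0), min=1.0)
            p.add("surround_amp", value=0.5 * rmax, min=0.0)
            # enforce center_sigma < surround_sigma via a positive ratio
            p.add("sigma_ratio", value=ss_ratio, min=1.001)
            p.add("surround_sigma", expr="center_sigma * sigma_ratio")
            try:
                res = minimize_quietly(
                    lambda pp: _dog_area(d, pp["center_amp"],
                                         pp["center_sigma"],
                                         pp["surround_amp"],
                                         pp["surround_sigma"]) - r,
                    p, method="least_squares")
            except Exception:
                continue
            rms = float(np.sqrt(np.mean(res.residual ** 2)))
            if best is None or rms < best[0]:
                best = (rms, res)
        if best is None:
            raise RuntimeError("DoG fit failed to converge")
        rms, res = best
        names = ("center_amp", "center_sigma", "surround_amp", "surround_sigma")
        v = {k: float(res.params[k].value) for k in names}
        e = {k: (float(res.params[k].stderr)
                 if res.params[k].stderr is not None else np.nan)
             for k in names}
        # suppression from the data (primary) and from the fitted curve
        supp_data = surround_suppression_percent(self.data)
        dense = np.linspace(d.min(), d.max(), 512)
        curve = _dog_area(dense, *[v[k] for k in names])
        c_opt = curve.max()
        supp_fit = (100.0 * (c_opt - curve[-1]) / c_opt if c_opt > 0 else np.nan)
        diag = {"rms": rms,
                "suppression_percent": supp_data,
                "suppression_percent_fit": supp_fit}
        return AreaResponseResults(self, v, e, diag)


class AreaResponseResults(Results):
    @property
    def suppression_percent(self) -> float:
        return self.diagnostics["suppression_percent"]

    def predict(self, d):
        p = self.params
        return _dog_area(np.asarray(d, float), p["center_amp"],
                         p["center_sigma"], p["surround_amp"],
                         p["surround_sigma"])


def fit_area_response(data: AreaResponse) -> AreaResponseResults:
    return AreaResponseModel(data).fit()


# ---------------------------------------------------------------------------
# Hill speed tuning (n fixed at 1)

def _hill(s, r_max, s50):
    return r_max * s / (s + s50)


@dataclass
class SpeedTuning:
    """Peak response versus stimulus speed."""

    speeds: np.ndarray     # um/s, strictly increasing
    responses: np.ndarray  # Hz

    def __post_init__(self):
        self.speeds = np.asarray(self.speeds, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.speeds.size != self.responses.size:
            raise ValueError("speeds and responses differ in length")
        if np.any(np.diff(self.speeds) <= 0):
            raise ValueError("speeds must be strictly increasing")


class SpeedTuningModel(Model):
    """Hill-equation fit R(s) = R_max s / (s + s50) with exponent 1."""

    def __init__(self, data: SpeedTuning):
        if data.speeds.size < 3:
            raise ValueError("need >= 3 speeds")
        self.data = data

    def fit(self) -> "SpeedTuningResults":
        s, r = self.data.speeds, self.data.responses
        p = lmfit.Parameters()
        p.add("r_max", value=max(r.max(), 1e-9) * 1.2, min=0.0)
        p.add("half_max_speed", value=float(np.median(s)), min=1e-6)
        res = minimize_quietly(
            lambda pp: _hill(s, pp["r_max"], pp["half_max_speed"]) - r,
            p, method="least_squares")
        if not res.success:
            raise RuntimeError("Hill fit did not converge")
        v = {k: float(res.params[k].value) for k in res.params}
        e = {k: (float(res.params[k].stderr)
                 if res.params[k].stderr is not None else np.nan)
             for k in res.params}
        rms = float(np.sqrt(np.mean(res.residual ** 2)))
        return SpeedTuningResults(self, v, e, {"rms": rms, "hill_n": 1})


class SpeedTuningResults(Results):
    @property
    def half_max_speed(self) -> float:
        return self.params["half_max_speed"]

    def predict(self, s):
        return _hill(np.asarray(s, float), self.params["r_max"],
                     self.params["half_max_speed"])


def fit_speed_tuning(data: SpeedTuning) -> SpeedTuningResults:
    return SpeedTuningModel(data).fit()
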