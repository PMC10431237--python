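"""Pipeline orchestration: configuration, stage wiring, the demo run.

Stages communicate through the flat-file formats in :mod:`retinophys.io`,
so any stage can be re-run alone on files written by a prior run.  The
``demo`` entry point executes the full synthetic chain — voltage-clamp
conductance decomposition, sEPSC detection and kinetics, DSGC direction
tuning, and IPL depth-profile alignment — from a single master seed,
and writes a deterministic results table plus report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import events as ev
from . import ihc
from . import stats as st
from . import synth
from . import tuning as tn
from . import vclamp as vc
from .report import ResultsTable, render_report, config_hash

__all__ = ["RunConfig", "run_demo", "load_config"]


@dataclass
class RunConfig:
    """Per-stage parameters with the standard experimental defaults.

    Defaults: reversal potentials 0 / -69 mV, 10-ms conductance
    analysis bins, derivative threshold at 5 noise SDs, 25-ms PSTH
    bins, ChAT anchors at 28% / 63% IPL depth, alpha = 0.05.
    """

    master_seed: int = 0
    # conductance stage
    e_exc: float = vc.DEFAULT_E_EXC
    e_inh: float = vc.DEFAULT_E_INH
    analysis_interval: float = vc.DEFAULT_ANALYSIS_INTERVAL
    junction_potential: float = vc.DEFAULT_JUNCTION_MV
    # event stage
    threshold_multiple: float = ev.DEFAULT_THRESHOLD_MULTIPLE
    min_separation: float = ev.DEFAULT_MIN_SEPARATION
    excision_window: Tuple[float, float] = ev.DEFAULT_EXCISION_WINDOW
    # tuning stage
    psth_bin_width: float = 0.025
    # ihc stage
    anchors: Tuple[float, float] = ihc.CHAT_ANCHORS
    # stats
    alpha: float = 0.05

    def __post_init__(self):
        if self.e_exc == self.e_inh:
            raise ValueError("e_exc must differ from e_inh")
        if self.analysis_interval <= 0 or self.psth_bin_width <= 0:
            raise ValueError("intervals must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Read a YAML config file; keys mirror RunConfig fields."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("excision_window", "anchors"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# demo stages (synthetic end-to-end run)

def _demo_conductance(cfg: RunConfig, table: ResultsTable, out: Path) -> None:
    seed = synth.derive_seed(cfg.master_seed, "vclamp")
    n, dt = 1000, 1e-3
    g_exc = synth.boxcar_with_transient(n, dt, onset=0.2, offset=0.7,
                                        sustained=0.75, transient=1.0,
                                        transient_tau=0.05)
    g_inh = synth.boxcar_with_transient(n, dt, onset=0.2, offset=0.7,
                                        sustained=1.0)
    from .stimulus import StimulusSpec
    stim = StimulusSpec(kind="spot", diameter=175.0, onset=0.2, offset=0.7)
    params = synth.VClampSimParams(g_exc_waveform=g_exc, g_inh_waveform=g_inh,
                                   e_exc=cfg.e_exc, e_inh=cfg.e_inh,
                                   noise_sd=4.0, sampling_interval=dt,
                                   seed=seed, stimulus=stim)
    family, truth = synth.simulate_vclamp_family(params)
    vc.write_family(out / "vclamp_family.tsv", family)
    net = vc.net_evoked_currents(family)
    res = vc.ConductanceModel(net, cfg.e_exc, cfg.e_inh,
                              cfg.analysis_interval).fit()
    vc.write_conductance(out / "conductance.tsv", res.conductance)
    peaks = vc.peak_conductance(res.conductance, (0.2, 0.9))
    table.add("conductance", "peak_g_exc_nS", peaks["exc"][0])
    table.add("conductance", "peak_g_inh_nS", peaks["inh"][0])
    table.add("conductance", "true_peak_g_exc_nS", float(g_exc.max()))
    table.add("conductance", "true_peak_g_inh_nS", float(g_inh.max()))


def _demo_events(cfg: RunConfig, table: ResultsTable, out: Path) -> None:
    seed = synth.derive_seed(cfg.master_seed, "sepsc")
    params = synth.SepscSimParams(duration=10.0, seed=seed)
    trace, true_times = synth.simulate_sepsc_trace(params)
    catalog = ev.detect_events(trace, cfg.threshold_multiple,
                               cfg.min_separation)
    avg = ev.average_events(trace, catalog, cfg.excision_window)
    decay = ev.fit_decay(avg)
    table.add("events", "event_frequency_per_s", ev.event_frequency(catalog))
    table.add("events", "true_frequency_per_s",
              true_times.size / params.duration)
    table.add("events", "tau_fast_us", decay.tau_fast * 1e6)
    table.add("events", "tau_slow_ms", decay.tau_slow * 1e3)
    table.add("events", "n_events_averaged", avg.n_events)


def _demo_tuning(cfg: RunConfig, table: ResultsTable, out: Path) -> None:
    seed = synth.derive_seed(cfg.master_seed, "dsgc")
    params = synth.DsgcSimParams(n_trials=3, seed=seed)
    stimuli = synth.drifting_bar_set()
    rasters, truth = synth.simulate_dsgc_raster(params, stimuli)
    angles, responses = [], []
    for r in rasters:
        psth = tn.build_psth(r, cfg.psth_bin_width)
        resp = (tn.integrate_response(psth, r.response_windows["on"])
                + tn.integrate_response(psth, r.response_windows["off"]))
        angles.append(r.stimulus.direction)
        responses.append(resp)
    curve = tn.TuningCurve(np.array(angles), np.array(responses))
    table.add("tuning", "preferred_direction_deg", curve.preferred_direction)
    table.add("tuning", "vector_dsi", curve.vector_dsi)
    table.add("tuning", "prefnull_dsi", curve.prefnull_dsi)
    table.add("tuning", "true_preferred_direction_deg",
              truth["preferred_direction_on"])


def _demo_ihc(cfg: RunConfig, table: ResultsTable, out: Path) -> None:
    seed = synth.derive_seed(cfg.master_seed, "ihc")
    groups = {"wt": 1.0, "stg": 0.6}
    aligned: Dict[str, list] = {g: [] for g in groups}
    for gi, (group, amp) in enumerate(groups.items()):
        for animal in range(3):
            ref_p = synth.ProfileSimParams(
                band_centers=(0.31, 0.60), noise_sd=0.01,
                seed=seed + 17 * gi + animal)
            tgt_p = synth.ProfileSimParams(
                band_centers=(0.31, 0.60), band_amplitudes=(amp, amp),
                noise_sd=0.01, seed=seed + 17 * gi + animal + 1000)
            ref, tgt, _ = synth.simulate_depth_profile(
                ref_p, tgt_p, group=group, animal=f"a{animal}")
            peaks = ihc.reference_band_peaks(ref)
            aligned[group].append(
                ihc.align_profile(tgt, peaks, cfg.anchors))
    means = {g: ihc.average_profiles(ps) for g, ps in aligned.items()}
    wt_peak = float(means["wt"].intensity.max())
    norm = {g: ihc.normalize_to_reference(m, wt_peak)
            for g, m in means.items()}
    diff = ihc.difference_profile(norm["wt"], norm["stg"])
    for band, anchor in zip(("off_band", "on_band"), cfg.anchors):
        a_vals = [p.value_at(anchor) / wt_peak for p in aligned["wt"]]
        b_vals = [p.value_at(anchor) / wt_peak for p in aligned["stg"]]
        cmp = ihc.compare_at_bands(a_vals, b_vals, n_comparisons=2,
                                   alpha=cfg.alpha)
        table.add("ihc", f"intensity_at_{band}", value=float(np.mean(a_vals)),
                  group_a="wt", group_b="stg", n_a=cmp.n_a, n_b=cmp.n_b,
                  statistic=cmp.t_statistic, p=cmp.p_value,
                  adjusted_alpha=cmp.alpha_adjusted)
        table.add("ihc", f"difference_at_{band}", diff.value_at(anchor))


def _demo_stats(cfg: RunConfig, table: ResultsTable, out: Path) -> None:
    rng = np.random.default_rng(synth.derive_seed(cfg.master_seed, "stats"))
    het = rng.normal(1.75, 0.8, size=20)
    stg = rng.normal(1.12, 0.3, size=20)
    cmp = st.compare_groups(het, stg, alpha=cfg.alpha)
    table.add("stats", "simulated_peak_g_exc", value=cmp.effect,
              group_a="het", group_b="stg",
              n_a=cmp.n_per_group[0], n_b=cmp.n_per_group[1],
              statistic=cmp.statistic, p=cmp.p_value,
              adjusted_alpha=cmp.alpha_adjusted)
    table.add("stats", "percent_change_peak_g_exc",
              st.percent_change(float(het.mean()), float(stg.mean()),
                                rounded=True))


_STAGES = {
    "conductance": _demo_conductance,
    "events": _demo_events,
    "tuning": _demo_tuning,
    "ihc": _demo_ihc,
    "stats": _demo_stats,
}


def run_demo(config: Optional[RunConfig] = None, out_dir="demo_run",
             stages: Optional[Sequence[str]] = None) -> Path:
    """Run the synthetic end-to-end pipeline; returns the report path."""
    cfg = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = ResultsTable()
    selected = list(stages) if stages else list(_STAGES)
    unknown = set(selected) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for name in selected:
        _STAGES[name](cfg, table, out)
    return render_report(table, out, seed=cfg.master_seed,
                         config=cfg.to_dict())
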