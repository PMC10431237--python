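# retinophys

Quantitative analyses for retinal circuit physiology, built as a tested,
reusable pipeline. The package covers four analysis families that are
usually re-implemented ad hoc in every electrophysiology lab studying
direction-selective retinal circuits:

1. **Synaptic conductance decomposition** — light-evoked currents
   recorded under voltage clamp at several holding potentials are
   decomposed into time-resolved excitatory and inhibitory conductances
   by least-squares fits to the current–voltage relation at each
   analysis time point, assuming linear synaptic conductances with
   fixed reversal potentials:

   `I_net(V, t) = g_E(t) (V − E_exc) + g_I(t) (V − E_inh)`,

   with `E_exc = 0 mV`, `E_inh = −69 mV`, fitted in 10-ms bins.

2. **Spontaneous EPSC analysis** — sEPSCs are detected by
   differentiating the current record and thresholding at 5 SDs of the
   derivative noise, excised and averaged, and the decay of the average
   event fitted with a double exponential
   `A_f e^(−t/τ_f) + A_s e^(−t/τ_s)`.

3. **Spike-train tuning of direction-selective ganglion cells** —
   PSTHs, ON/OFF response integration, preferred direction and DSI by
   vector sum (`|Σ r_k e^{iθ_k}| / Σ r_k`) and by
   `(R_pref − R_null)/(R_pref + R_null)`, von Mises tuning fits,
   difference-of-Gaussians area-response fits with surround-suppression
   estimates, and Hill speed-tuning fits with exponent fixed at 1.

4. **IPL depth-profile analysis** — mean-gray-value fluorescence
   profiles across the inner plexiform layer are anchored to the OFF
   and ON ChAT (starburst amacrine cell) bands at 28% and 63% IPL
   depth by a piecewise-linear depth warp, then averaged hierarchically
   (image → animal → group), normalised to the wild-type session peak,
   and compared between groups at the band depths.

Every analysis has a matching synthetic-data generator
(`retinophys.synth`) with known ground truth, so the whole pipeline is
testable end to end without any recordings. Fits follow a
Model/Results pattern: construct a model from data, call `fit()`, and
read estimates, standard errors and diagnostics off the results object
(or print `summary()`).

## Worked example

Simulate an eight-potential voltage-clamp family (holding potentials
−90 … +50 mV in 20-mV steps) with a transient-plus-sustained excitatory
conductance peaking at 1.75 nS, a 1 nS inhibitory boxcar and 4 pA
noise, then recover the conductances:

```python
import numpy as np
from retinophys import synth, vclamp as vc
from retinophys.stats import percent_change

n, dt = 1000, 1e-3
g_exc = synth.boxcar_with_transient(n, dt, onset=0.2, offset=0.7,
                                    sustained=0.75, transient=1.0,
                                    transient_tau=0.05)
g_inh = synth.boxcar_with_transient(n, dt, onset=0.2, offset=0.7,
                                    sustained=1.0)
params = synth.VClampSimParams(g_exc_waveform=g_exc, g_inh_waveform=g_inh,
                               noise_sd=4.0, sampling_interval=dt, seed=1)
family, truth = synth.simulate_vclamp_family(params)

net = vc.net_evoked_currents(family)
res = vc.ConductanceModel(net, e_exc=0.0, e_inh=-69.0, interval=0.010).fit()
print(res.summary())
```

```
ConductanceResults
==================
               estimate  std_err
parameter
peak_g_exc_nS   1.66996      NaN
peak_g_inh_nS   1.01615      NaN
------------------
mean_residual_rms_pA: 1.10465
n_potentials: 8
n_bins: 100
e_exc_mV: 0
e_inh_mV: -69
```

The recovered peak excitatory conductance, 1.67 nS, matches the
ground-truth waveform averaged into the 10-ms analysis bins (1.67 nS;
the unbinned instantaneous peak is 1.75 nS), and the recovered
inhibitory plateau is 1.02 nS against a true 1.00 nS. The residual RMS
(~1.1 pA) reflects the injected recording noise after bin averaging.
Percent reductions between group means are one call:

```python
percent_change(1.75, 1.12, rounded=True)   # -> 36.0 (% reduction)
```

The same pattern runs the other stages: `events.detect_events` →
`events.average_events` → `events.DecayModel(...).fit()`;
`tuning.build_psth` → `tuning.TuningCurve` →
`tuning.VonMisesModel(...).fit()`; `ihc.find_band_peaks` →
`ihc.align_profile` → `ihc.average_profiles` →
`ihc.difference_profile`.

## Command line

A thin CLI wraps the library; the `demo` subcommand runs the full
synthetic chain from a single master seed and writes a deterministic
results table, report and provenance record:

```sh
retinophys demo --seed 1 --out demo_run
retinophys simulate --kind vclamp --seed 2 --out family.tsv
retinophys conductance family.tsv --out conductance.tsv
```

All stage hand-offs use flat TSV files with `#`-prefixed metadata
headers, so any stage can be re-run alone on files from a prior run.

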