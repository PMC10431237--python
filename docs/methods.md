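# Methods

This note documents the models implemented in `retinophys`, the
defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical choices that affect results.

## Stimulus bookkeeping

Two contrast conventions coexist in retinal physiology and both are
provided. Weber contrast, `100 (L_stim − L_back)/L_back`, describes
increments/decrements on a steady background (the standard spot
protocol: background 150 units, dark spots 30 → −80%, bright spots
270 → +80%). Michelson contrast, `100 (L_max − L_min)/(L_max + L_min)`,
describes modulated stimuli. Intensities can carry either of two unit
tags (μW/m² or photons/μm²/s); contrast is unit-free, but mixing tags
raises rather than silently converting — no radiometric-to-photon
conversion is attempted because it depends on the spectrum.

Directions are degrees, counterclockwise, 0° along the +x axis of the
recording frame, normalised to [0, 360). This is a package-wide
convention; recordings define no canonical frame.

## Conductance decomposition

The model assumes the light-evoked current is the sum of *linear*
excitatory and inhibitory synaptic conductances with fixed reversal
potentials (defaults 0 and −69 mV, the cation and chloride reversals
for the standard cesium-methanesulfonate internal solution):

    I_net(V, t) = g_E(t)(V − E_exc) + g_I(t)(V − E_inh)

- **Junction correction.** A liquid junction potential (default
  −10 mV) is subtracted from command voltages once; re-application is
  an error. Holding potentials default to −90…+50 mV in 20-mV steps.
- **Baseline.** Each trace's own baseline mean over a window (default
  the 100 ms before stimulus onset) is subtracted as a scalar. For a
  stationary leak this is equivalent to subtracting a fitted leak line
  and is robust to misestimating the leak reversal.
- **Analysis bins.** Raw samples are *averaged* within 10-ms bins
  before the per-bin least-squares solve (averaging beats decimation
  for noise, and the binned estimate is then the fit to the binned
  ground truth exactly).
- **No rectification.** Fitted conductances are reported unclipped;
  negative values are a diagnostic of model violations (e.g. NMDA- or
  spermine-dependent nonlinearity), not an error to hide. Reversals
  are fixed by default; refitting them per cell is possible by calling
  the model with different values, but is deliberately not automatic.
- **Peaks.** Peak conductance is the maximum of each component in a
  response window (default stimulus onset to offset + 200 ms), ties
  broken to the earliest time.
- **Subtraction.** Pharmacological (control − drug) and group
  (control − mutant) differences are pointwise per component and
  require identical time bases and reversals; no resampling is
  implied.

With ≥ 2 distinct potentials and zero noise the decomposition is an
exact linear solve; the round trip simulator → decomposition recovers
the bin-averaged input waveforms to machine tolerance, and with noise
the peak estimates are unbiased (checked over 200 seeded repeats).

## Spontaneous EPSC analysis

- **Detection.** The record is differentiated by first differences;
  the derivative noise SD is estimated as 1.4826 × the median absolute
  deviation over the whole record, which is robust to the events
  themselves (the measurement of "the noise" is not otherwise
  specified by convention). Events are crossings of
  `threshold_multiple` (default 5) × SD in the inward direction;
  crossings within `min_separation` (default 5 ms) of an accepted
  event are collapsed; the event time is the first crossing sample.
  This detector intrinsically favours large, fast events; no
  correction is applied.
- **Averaging.** Segments over a (−10 ms, +250 ms) window are excised,
  each baseline-subtracted by its own pre-window mean, and averaged.
  The post-window must span several slow time constants (τ_s ~ 50 ms)
  for the slow decay to be fittable. Alignment is on the
  threshold-crossing time (peak alignment is available as an option).
- **Decay fit.** From the extremum of the average onward, a double
  exponential is fitted by multi-start nonlinear least squares;
  components are ordered τ_f < τ_s, and near-equal time constants or a
  vanishing amplitude flag the fit as degenerate (effectively
  single-exponential).
- **Frequency.** Count/duration per cell; group frequency is reported
  both pooled (total events / total time, the default) and as the mean
  of per-cell rates — the two differ when cells contribute unequal
  durations, and outputs name which was used.

**Known bias.** When the underlying event has a non-instantaneous rise
(the generator uses a 200-μs rise time constant), the decay phase at
the peak still contains a residual rise term, which inflates the
fitted τ_f relative to the generative decay constant (by ~30% at
τ_f ≈ 460 μs). This mirrors what any peak-onward biexponential fit
does to real events with slow rises; fitted time constants are
estimates of the *decay-phase* kinetics, not deconvolved channel
constants. The estimator itself is validated on pure biexponential
decays, where recovery is <1% noiseless across
τ_f ∈ [200 μs, 1 ms] × τ_s ∈ [10, 100] ms (excluding the degenerate
corner where τ_f equals the rise constant and the fast component
vanishes by construction).

## DSGC tuning

- **PSTH.** Spikes pooled over trials, rate = count/(n_trials ×
  bin width). Bin width defaults to 25 ms (unstated by convention;
  recovery properties hold for 10–50 ms).
- **Responses.** Spikes/trial by integrating the PSTH over the ON
  (trailing edge) and OFF (leading edge) response windows for dark
  bars (roles swap for bright bars); windows are computed from bar
  geometry and speed (edge crossing time ± 3 temporal SDs of the
  receptive-field passage) with manual override. Peak rate is the
  maximum PSTH bin in the window, with the time point logged.
- **DSI.** Two definitions are computed and always named explicitly:
  the normalised vector-sum length (in [0, 1]) with the preferred
  direction as the resultant angle, and
  (R_pref − R_null)/(R_pref + R_null) with R_null at the measured
  angle nearest 180° from preferred (exact on the standard 12 × 30°
  grid). Uniform responses leave the preferred direction undefined
  (NaN) with vector DSI 0. The vector DSI has a positive small-sample
  bias on untuned data; with 40 trials its median stays ≤ 0.1.
- **von Mises fit.** `R(θ) = baseline + amplitude·exp(κ(cosΔ − 1))`,
  the peak-normalised parameterisation, so `amplitude` is the peak
  above baseline at θ = μ. Flat fits (κ < 0.1 or negligible
  amplitude) are flagged untuned.
- **Area-response fit.** The disc-integrated difference-of-Gaussians
  `R(d) = A_c(1 − e^{−d²/2σ_c²}) − A_s(1 − e^{−d²/2σ_s²})` (the
  stimuli are filled spots, so the area-summation form, not a raw
  Gaussian difference in diameter); σ_c < σ_s is enforced through a
  ratio parameter. Surround suppression is
  `100 (R_opt − R_largest)/R_opt` computed on the *data points* so it
  is defined even when the fit is poor; the fit-based variant is also
  reported.
- **Speed tuning.** Hill fit `R(s) = R_max·s/(s + s₅₀)` with the
  exponent fixed at 1; s₅₀ is the half-maximal speed.

## IPL depth profiles

Depth is expressed as 0% at the INL border, 100% at the GCL border.
The OFF and ON ChAT bands at 28% and 63% depth are the fiducials.

- **Projection/extraction.** Maximum-intensity projection of the
  central k of n z-slices (default 3 of 5); mean gray value across the
  ROI width per depth row; depth rescaled to % IPL between
  user-supplied IPL bounds (automatic layer segmentation is out of
  scope).
- **Peak detection.** Gaussian smoothing with SD = 2% of IPL depth,
  then downward zero crossings of the first derivative with negative
  second derivative. Candidates are ranked by prominence measured on
  the smoothed profile and refined to the raw-profile maximum within
  the smoothing window — the refinement removes the localisation bias
  smoothing introduces on asymmetric (warped) bands. For ChAT
  references the two most prominent peaks are the anchors; for
  calretinin references the outermost and innermost bands are used.
  Bands closer than about twice their SD merge into a single maximum
  and cannot be separated by any detector; the two-band guarantee
  assumes resolvable bands.
- **Alignment.** A piecewise-linear depth warp with pinned endpoints
  (0→0, 100→100) and interior knots (outer peak→28, inner peak→63),
  strictly monotone for any valid peak pair; intensities are resampled
  by linear interpolation onto a common 101-point grid (0–100% in 1%
  steps). Whether the warp outside the anchors should be
  endpoint-pinned pieces or one affine map is undetermined by
  convention; the pinned-piecewise choice is recorded in profile
  metadata. The *reference channel's* warp is applied identically to
  the co-registered target channel.
- **Averaging and normalisation.** Aligned profiles average
  image → animal → group (the group SEM is over animals, not pooled
  images). Mutant profiles are normalised once to the wild-type
  session peak; double normalisation is an error. Group differences
  are pointwise on the common grid, and per-band comparisons are
  unpaired t tests at the anchor depths with Bonferroni adjustment.

## Statistics battery

`compare_groups` applies a Shapiro–Wilk gate (p < 0.05 on either
group → Mann–Whitney U for unpaired data), then a two-tailed t test,
Welch-corrected when a variance-ratio F test rejects equality at 0.05
(the "where necessary" gating rule is not standardised; the F-test
criterion is used and logged in the result). Paired data use the
paired t test. Mean differences are reported with 95% CIs;
significance is judged at α/Bonferroni-divisor. Zero-variance groups
are flagged degenerate rather than tested. The gated battery's type-I
error at α = 0.05 on null normal samples stays within [0.03, 0.07]
(checked over 1,000 simulations). Repeated-measures ANOVA for the
speed/width designs is delegated to statsmodels' AnovaRM and flagged
as delegated.

## Synthetic-data generators

The generators exist to give every stage a ground truth; their
defaults are the study conditions the analyses target.

- **Voltage clamp:** `I(t;V) = g_leak(V−E_leak) + g_E(t)(V−E_exc) +
  g_I(t)(V−E_inh)` + white Gaussian noise; 8 potentials −90…+50 mV;
  leak 2 nS around −60 mV; conductance templates are boxcars with an
  optional exponential onset transient. No series-resistance or
  space-clamp artifacts are modelled, so passing recovery tests bounds
  estimator error, not clamp-quality error in real cells.
- **sEPSC trains:** homogeneous Poisson events (default 14.8/s over
  38 s) of kernels
  `−[A_f(e^{−t/τ_f} − e^{−t/τ_r}) + A_s(e^{−t/τ_s} − e^{−t/τ_r})]`
  with τ_r = 200 μs, τ_f = 464 μs, τ_s = 53 ms, A_f = 20 pA,
  A_s = 5 pA (amplitudes chosen at the scale of amacrine-cell sEPSCs;
  only the time constants are pinned by the reference condition),
  riding on low-pass (2 Hz) Gaussian baseline wander (3 pA SD) plus
  0.5 pA white noise, sampled at 10 kHz. Fast and slow release are
  uncorrelated by default (whether they should be correlated is
  configurable by passing explicit event times).
- **DSGC rasters:** inhomogeneous Poisson spiking; rate = baseline +
  ON and OFF Gaussian temporal envelopes centred on trailing/leading
  edge crossings of the receptive-field centre (RF SD 50 μm, travel
  path 1.2 mm), scaled by von Mises direction factors, a Hill speed
  factor (n = 1; s₅₀ = 1000 μm/s narrow, 500 μm/s wide), and a single
  multiplicative wide-bar surround factor (1 − surround_weight) — a
  deliberate simplification sufficient to exercise the width
  comparisons, not a spatial surround model. Ground truth includes
  the analytically expected ON/OFF spikes/trial per stimulus
  (Gaussian envelope mass inside each window, including cross-envelope
  overlap, plus baseline).
- **Depth profiles:** baseline + Gaussian bands + pixel noise on a
  201-sample depth grid; the reference channel has exactly two bands.
  A minimal renderer tiles profiles into a small two-channel TIFF
  z-stack purely to exercise image ingestion — it does not emulate
  real micrographs (no puncta, no depth-dependent background, no
  attenuation).

All generators are bit-reproducible from an integer seed; a master
seed derives per-stage sub-seeds via a CRC of the stage label.

## Problem sizes in the test suite

The suite validates recovery at sizes chosen to keep the full run in
seconds while leaving sampling error well below the tolerances tested:
200 seeded repeats for conductance-peak bias, 20 × 10-s records for
detection recall/false positives, 40-trial rasters (50 seeds for the
untuned-limit check), and 1,000 null simulations for the type-I-error
calibration.

## Known limitations

- The conductance model is linear by construction; voltage-dependent
  conductances appear as negative or non-additive fitted components.
- Detection recall is scored with a ±min_separation matching window;
  events closer than min_separation are intentionally merged by the
  collapse rule and cannot be counted separately.
- Fitted τ_f from peak-onward decay fits overestimates the generative
  decay constant when rise and decay time scales are comparable (see
  above).
- Profile alignment assumes two resolvable reference bands; merged
  bands raise rather than guess.
- The surround model in the DSGC generator is multiplicative, so
  surround-suppression *mechanisms* (timing, spatial extent) are out
  of its reach; only the suppression magnitude is emulated.
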