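# Methods

This note documents the models, conventions and numerical choices behind
`assrlab`, and what the synthetic-data generator does and does not
emulate.

## Stimulus model

The probe is a 400-Hz tone with raised-cosine amplitude modulation at
f_m = 40 Hz: within each burst the envelope is
`0.5·(1 − cos(2π f_m t_local))` with `t_local` measured from the burst
onset. This convention makes the modulation start at exactly zero at
every onset ("modulated between 0 and 100%"), and because the 12.5-ms
silent gaps equal half a modulation period, consecutive bursts are
mutually phase-continuous. Five 400-ms bursts give a 2050-ms AM sound;
onsets fall at k·412.5 ms. The audio rate defaults to 25 kHz, an integer
multiple of the 1250-Hz MEG rate.

The babble masker is a statistical surrogate: four independent
speech-shaped noise streams (flat to 500 Hz, −9 dB/octave above), each
multiplied by its own 2–8 Hz syllabic-rate envelope, summed,
notch-filtered in the octave around the carrier and shaped with 200-ms
cosine ramps (3050-ms total, leading/trailing the AM sound by 500 ms).
Only its notch/SNR/duration contracts are guaranteed; no claim is made
about higher-order resemblance to recorded multi-talker speech. The
notch is a 3001-tap kaiser-window FIR (−6 dB at 283/566 Hz, measured
−103 dB at 400 Hz); the design function raises if the realized response
misses the template. SNR is defined over the AM-sound interval as
`10·log10(P_AM/P_masker)` and calibrated by rescaling the masker only.

All filters in the package are applied with exactly zero phase by
multiplying the signal spectrum with the FIR's magnitude response. For a
linear-phase FIR this equals filtering plus exact (fractional-sample)
delay removal; it keeps latency estimates free of filter delay, which
matters because the group contrasts of interest are a few milliseconds.

## Synthetic cohort

Cohort covariates follow linear structural equations with Gaussian
residuals, so every configured slope is identifiable by OLS and the
generating truth is retained for recovery tests. Defaults encode the
study conditions: ages ~76.1 ± 6.2 y (older) and 23.8 ± 3.0 y (young,
truncated to the group ranges); hearing thresholds rising 1.5 dB/year
within the older group; SIN loss rising 0.35 dB/year; right-hemisphere
total GABA falling 0.012 units/year; quiet/noise 40-Hz amplitudes of
3.66/1.04 nAm (young) and 3.37/1.63 nAm (older) with age slopes of
0.16 and 0.12 nAm/year in the older group; quiet laterality 0.13, noise
0.03; a 4.39-ms mean older-group response delay with condition deltas of
−1.52 ms (young) and −3.25 ms (older) for noise relative to quiet; and
200/240-ms amplitude buildup in quiet/noise. Residual SDs are set so the
within-older-group correlations are of the magnitude seen in aging
cohorts of this size (e.g. R² ≈ 0.7 for PTA–age). Correlations between
measures arise only through shared structural paths; a null configuration
(all slopes zero) yields mutually independent covariates.

Amplitude bookkeeping: configured group means are on the measurement
scale (what the 40-Hz estimator reports). Stored per-participant source
amplitudes are peak moments, i.e. the measured-scale draw divided by the
estimator gain N/(2(N−1)) ≈ 0.5027 (see below), so that the full chain
reads back the configured numbers.

## Sensor-level simulation

Current dipoles in a spherical conductor (radius 90 mm) are evaluated
with the closed-form sphere solution, so radial moments are exactly
silent; sensors are 151 axial gradiometers (two-point difference along
the radial normal, 50-mm baseline) on a Fibonacci-spiral helmet cap of
radius 110 mm, with one channel disabled (150 usable). The helmet is a
synthetic layout: real gradiometer geometries are vendor-specific and
not required by any contract here. Default sources sit at ±(48, −17, 8)
mm with mostly tangential, mirror-symmetric orientations.

The entrained moment restarts its 40-Hz oscillation at each burst onset
(phase-locked to the stimulus with the participant's lag), with a linear
amplitude ramp over `buildup_ms` from each onset; the quiet condition
adds a slow damped onset transient. Because onsets are 16.5 modulation
periods apart, a single continuous oscillation would alternate phase by
π between bursts — the restart is what makes the five analysis windows
phase-consistent, and it matches the waveform resets seen in the data
this generator emulates.

Noise and artifacts are free parameters with these defaults: white
sensor noise of 6 fT/√Hz with a 1/f component below 5 Hz; an 8-nAm 1/f
background in each source; blinks at 0.2/s (300-ms squared-Hann
transients, frontal Gaussian topography, 2 pT); heartbeats at 1.1 Hz
with 5% interval and 10% amplitude jitter (a stereotyped multiphasic
~120-ms template with a fixed broad random topography, 0.6 pT). The
levels are chosen so that single sub-averages at the study's trial count
(75 trials × 3 epoch types) explain ≥ 90% of field variance with a
dipole pair, while single trials do not — i.e. averaging is necessary,
as in real recordings. The ground-truth sidecar stores moments, artifact
times and geometry, sufficient to rebuild the noiseless recording
exactly.

What the generator does not emulate: cortical geometry and realistic
head models, sensor cross-talk, environmental noise, eye movements other
than blinks, ECG morphology, or head movement within a block (positions
drift only between the pre/post measurements). Passing tests therefore
validate the analysis logic and its calibration, not robustness to every
property of real MEG.

## Preprocessing

Motion: a block is rejected if any head-coil coordinate differs by more
than 4 mm (strict inequality) between the pre- and post-block
measurements.

Ocular: ICA on the 20 most anterior channels ("frontal" is defined by
the y coordinate; no channel list exists for a synthetic helmet).
Components are ranked by kurtosis × low-frequency (< 6 Hz) power
fraction — blinks are sparse and slow — and the top two are 6-Hz
low-pass filtered and regressed out of all channels. The low-pass is
what protects the 40-Hz band: the regressors carry no gamma energy, and
the measured downstream amplitude bias of full preprocessing is ~1%.

Cardiac: ICA over all channels (unmixing estimated on 5× decimated data
— mixing is instantaneous, so the weights transfer to full rate — which
cuts cost fivefold). Periodicity scoring is a real cepstrum of the
Welch-averaged log spectrum of each component's energy envelope,
smoothed to the jitter-broadened peak width, scored as peak height over
the surrounding 0.6–1.6 s quefrency background in robust (MAD) SDs. The
envelope is used because interval jitter scrambles the phase of the high
harmonics carrying the beat waveform itself, while the beat-rate
fundamental of the energy envelope survives; on simulated data genuine
beat trains score ≈ 25–30 where pure-noise components reach ≈ 5, and the
detection threshold is 8. Beats are peaks of the selected component;
the beat-locked sensor average — computed on the residual after
subtracting the trial-locked evoked model, so the template cannot absorb
stimulus-locked 40-Hz signal — forms a template subtracted with a
per-channel least-squares scale at every beat.

## Dipole fitting and projection

Sub-averages (all C(5,3) = 10 combinations of the five 500-ms onset
epochs per block; 40 with four blocks) are fitted after restricting the
field to the 28–56 Hz band, since the model is defined by the 40-Hz
activity. The bilateral fit is spatiotemporal: one position and one
orientation per hemisphere fixed over the epoch, moment amplitudes free
per sample. Positions are optimized by Nelder-Mead on one hemisphere at
a time (the other held fixed), alternating until both move < 0.1 mm or
50 alternations; during the search the moment vector is left free
(6-column lead field) for a smooth objective, and the final orientation
is the dominant singular vector of each dipole's moment block. Positions
are penalized outside 95% of the sphere radius. Initialization is the
mirror pair ±(50, −20, 10) mm.

Acceptance is two-stage and applied once: (1) variance explained ≥ 0.90;
(2) per hemisphere, position within two standard deviations of the
stage-1 mean, where the positional SD is the RMS distance from the mean
(using the SD of the distances themselves would reject arbitrarily tight
clusters). The model is the mean of surviving positions/orientations.
Source projection multiplies each −500…+2500 ms trial by the
pseudoinverse of the two patterns, preserving nAm units; the noiseless
round trip reproduces a 3.5-nAm moment to < 1e-6 relative error.

## The 40-Hz statistic

Trials are averaged, the pre-stimulus (500 ms) mean subtracted, the
average filtered with a 512-tap FIR whose applied −3-dB edges are
28.0/56.0 Hz (cutoffs tuned by bisection), and the analytic signal taken
by Hilbert transform. The estimator demodulates the real part over the
samples with onset-relative time in [250, 400] ms — exactly N = 188 at
1250 Hz — normalized by 1/(N−1) as printed, for each of the five onsets,
with t_n measured from each window's own onset; windows are anchored to
the nearest sample but use exact fractional onset times, keeping the
five window phases mutually consistent. The five complex values are
averaged as complex numbers (an `angle_mean` switch provides the
mean-angle alternative; on phase-consistent input the two agree).

On a unit sinusoid the estimator reads N/(2(N−1)) ≈ 0.5027 (the ½ from
demodulating a real cosine, ×N/(N−1) from the printed normalization,
plus ~0.3% self-leakage of the finite window). All recovery tests use
this gain explicitly.

Phase conventions: the reported `phase` is the argument of the complex
value, which *decreases* as the response is delayed (the demodulator is
e^(−i2πf t)). Latency arithmetic uses the delay-scale phase
(`phase_delay = −phase`, wrapped), so that Δt = Δφ/(2π f_m) is positive
when the comparison lags the reference; the wrap into (−π, π] makes
contrasts unambiguous only below half the 25-ms period, which covers the
few-ms group effects of interest. A Hilbert-route phase (circular mean
angle of the demodulated analytic signal over the same windows) is also
reported and agrees with the DFT phase to < 0.05 rad on clean input;
latency contrasts may use either.

Significance: the null of no phase locking is simulated by rotating each
trial's complex contribution by an independent uniform phase — valid
because every preparation step is linear, so the estimate of the average
equals the average of per-trial estimates. p = (1 + #{null ≥ observed})/
(n_resamples + 1), floored at 1/(n+1). Empirical null rejection at
α = 0.05 is nominal (0.047 over 1000 runs, KS-uniform p = 0.36).

## Group statistics

The mixed ANOVA implements the textbook split-plot decomposition for two
within factors (hemisphere, condition) crossed with one between factor
(age group); each within effect is tested against its subject-
interaction error term; effect size is generalized η² with all
subject-error sums of squares in the denominator. It is verified against
a brute-force sums-of-squares oracle and against an independent
implementation on the collapsed single-within design. Two-sample
contrasts default to Welch. The psychometric SNR₅₀ is a two-parameter
logistic fitted by maximum likelihood on (level, proportion-correct)
pairs; SIN loss is SNR₅₀ relative to the −2 dB norm. Mediation uses OLS
paths (c = c′ + a·b holds exactly) with case-resampling percentile
bootstrap CIs and two-sided sign-crossing p-values; the percentile
flavor was chosen as the simplest member of the family, and no
multiple-testing correction is applied by default.

## Pipeline and problem sizes

`run_study` drives the sensor-level chain per participant;
`run_source_level_study` computes the statistic directly on simulated
source waveforms, which is the appropriate tool for cohort-level
questions once the forward–inverse round trip is validated separately.
Block order alternates quiet/noise. Tests and the acceptance script use
scaled-down problem sizes chosen for desk-scale runs: plumbing tests run
1+1 participants × 1 block × 16 trials with reduced noise (the
GOF ≥ 0.90 criterion is signal-to-noise limited and is demonstrated at
the full 75-trial scale in the acceptance script); cohort statistics use
19+19 participants × 40 trials at source level; slope recovery uses
n = 2000 to beat sampling noise. The full-scale default (19+19 × 8
blocks × 75 trials through the sensor chain) is supported but is an
hours-long run.

## Known limitations

- The spherical conductor and synthetic helmet mean absolute field
  magnitudes are only order-of-magnitude realistic; all contracts are on
  recovery, ratios and calibration, not absolute tesla values.
- Ocular component selection is heuristic (kurtosis × slowness); on
  pathological mixtures it may pick fewer than two components, in which
  case it regresses what it found and warns.
- The cardiac detector requires ≥ 60 s of data and a quasi-periodic
  artifact; it deliberately skips removal (with a warning) rather than
  subtracting a dubious template.
- Mediation p-values are bootstrap sign-crossing probabilities, which
  are conservative near zero indirect effects.
- The 2-SD spatial acceptance can drop legitimate tail fits when the fit
  scatter is genuinely Gaussian (~2% of fits); this mirrors the rule it
  implements rather than a defect.
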