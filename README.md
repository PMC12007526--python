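# assrlab

Simulation and analysis of 40-Hz auditory steady-state responses (ASSR)
in MEG.

When a tone is amplitude-modulated at 40 Hz, auditory cortex entrains a
gamma-band oscillation phase-locked to the modulation. The strength and
latency of this entrained response change with age, with hearing and
speech-in-noise (SIN) ability, and with cortical GABA levels, which makes
the 40-Hz ASSR a compact probe of inhibition-dependent cortical timing.
`assrlab` implements the full analysis chain of such a study — from
stimulus synthesis to group statistics — together with a synthetic-data
generator that emulates the cohort and the sensor-level recordings, so
every stage can be exercised and validated without access to human data.

The pipeline:

1. **stimulus** — a 400-Hz carrier, 100% sinusoidally AM at
   f_m = 40 Hz, presented as five 400-ms bursts separated by 12.5-ms gaps
   (2050 ms total); a four-talker babble surrogate notch-filtered in the
   octave around the carrier (−6 dB at 283/566 Hz, < −60 dB at 400 Hz),
   mixed at +6 dB SNR.
2. **synthetic cohort & MEG** — young (19–28 y) and older (69–87 y)
   groups with structured covariates (PTA, SIN loss, GABA), and forward
   simulation of bilateral auditory-cortex dipoles through a spherical
   conductor onto a 151-channel axial-gradiometer helmet at 1250 Hz, plus
   1/f noise, ocular and quasi-periodic cardiac artifacts.
3. **preprocess** — ±4-mm head-motion screening, frontal-ICA blink
   regression (6-Hz low-passed regressors), cepstrum-guided cardiac
   template subtraction.
4. **sourcefit** — onset-locked 500-ms epochs, the ten 3-of-5 epoch-type
   sub-averages per block, alternating bilateral spatiotemporal dipole
   fits, two-stage acceptance (variance explained ≥ 0.90, position within
   2 SD), and least-squares source projection to left/right moment
   waveforms in nAm.
5. **assr** — the complex statistic

       ASSR = 1/(N−1) · Σₙ x(tₙ) · e^(−i·2π·f_m·tₙ)

   over the N = 188 samples in the 250–400 ms window after each of the
   five burst onsets (complex-averaged); amplitude = |ASSR|, phase =
   arg ASSR; phase-randomization bootstrap for per-participant
   significance; latency contrasts Δt = Δφ/(2π f_m); laterality index
   (R−L)/(R+L).
6. **stats** — mixed-design ANOVA with generalized η², OLS linear models,
   Welch/paired contrasts, logistic SNR₅₀ psychometric fits, and
   bootstrap mediation (a, b, c, c′, indirect = a·b).

## Worked example

Estimate one simulated participant's right-hemisphere ASSR in quiet and
in babble, with bootstrap significance:

```python
import numpy as np
from assrlab import assr
from assrlab.cohort import ParticipantSpec, SourceParams
from assrlab.simulate import trial_source_waveforms
from assrlab.stimulus import StimulusSpec

p = ParticipantSpec(
    id="s01", group="older", age=74.0, pta_db=27.0, sin_loss_db=5.1,
    gaba={}, sources={"quiet": SourceParams(7.0, 7.6, 52.4, 200.0, True),
                      "noise": SourceParams(3.2, 3.3, 49.1, 240.0)})

stim, fs = StimulusSpec(), 1250.0
for cond in ("quiet", "noise"):
    trials = np.stack([
        trial_source_waveforms(p, cond, stim, seed=i,
                               background_rms_nAm=8.0)["right"]
        for i in range(75)])
    est = assr.compute_assr(assr.prepare_average(trials, fs), fs)
    boot = assr.bootstrap_significance(trials, fs, n_resamples=1000, seed=0)
    print(f"{cond:6s} amplitude {est.amplitude:5.2f} nAm   "
          f"phase {est.phase:+6.3f} rad   p = {boot.p_value:.4f}")
```

prints

```
quiet  amplitude  3.82 nAm   phase -0.605 rad   p = 0.0010
noise  amplitude  1.66 nAm   phase +0.233 rad   p = 0.0010
```

The participant's configured sources (7.3 and 3.25 nAm hemisphere means,
times the estimator gain N/(2(N−1)) ≈ 0.503) are read back as ≈ 3.7 and
≈ 1.6 nAm against the 8-nAm 1/f background; both responses exceed every
phase-randomized null sample (p = 1/1001). Converting the phase
difference between conditions with Δt = Δφ/(2π·40 Hz) shows the quiet
response lagging the noise response by ~3.3 ms, and the babble attenuates
the amplitude by ~57% — both reflecting this participant's configured
latency and amplitude parameters.

The full study (cohort → recordings → cleaning → dipoles → ASSR → group
statistics) runs from the command line:

```sh
assrlab run-all --out results/ --seed 7 --n-young 19 --n-older 19 \
    --source-level          # fast path without the sensor stage
```

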