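"""Forward simulation of sensor-level MEG recordings.

Each participant's recording is built as the superposition of

* bilateral 40-Hz entrained dipole sources in auditory cortex, with
  configurable amplitude, phase lag, and post-onset amplitude buildup,
* 1/f-plus-white instrument/brain background noise per channel,
* ocular blink artifacts (slow frontal transients at ~0.2/s), and
* quasi-periodic cardiac artifacts (a stereotyped multiphasic template at
  ~1.1 Hz with beat-interval and amplitude jitter, broad fixed topography).

A ground-truth sidecar records every drawn quantity so that recovery and
artifact-removal tests can compare against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import ParticipantSpec, SourceParams
from .forward import HeadModel, SensorArray, forward_field
from .stimulus import StimulusSpec

__all__ = [
    "ArtifactConfig", "SensorRecording", "entrained_moment",
    "trial_source_waveforms", "simulate_block", "simulate_participant",
    "simulate_recording", "DEFAULT_POSITIONS_MM", "DEFAULT_ORIENTATIONS",
]

FS_MEG = 1250.0
TRIAL_PRE_MS = 500.0
TRIAL_POST_MS = 2500.0

#: default bilateral auditory-cortex dipole positions, head coordinates (mm)
DEFAULT_POSITIONS_MM = {"left": np.array([-48.0, -17.0, 8.0]),
                        "right": np.array([48.0, -17.0, 8.0])}
#: mostly tangential default orientations (mirror-symmetric pair)
DEFAULT_ORIENTATIONS = {"left": np.array([-0.2, 0.92, 0.33]),
                        "right": np.array([0.2, 0.92, 0.33])}


@dataclass
class ArtifactConfig:
    """Free parameters of the noise and artifact generators."""

    noise_floor_fT_sqrtHz: float = 6.0   # white sensor-noise density
    pink_knee_hz: float = 5.0            # 1/f noise matches floor at knee
    background_rms_nAm: float = 8.0      # broadband 1/f source background
    blink_rate_hz: float = 0.2
    blink_amp_fT: float = 2000.0
    blink_width_ms: float = 300.0
    cardiac_rate_hz: float = 1.1
    cardiac_interval_jitter: float = 0.05
    cardiac_amp_fT: float = 600.0
    cardiac_amp_jitter: float = 0.1
    head_drift_mm: float = 0.5


@dataclass
class SensorRecording:
    """One block of simulated MEG: usable channels x samples, in tesla."""

    data: np.ndarray
    fs: float
    events: list[tuple[int, str]]          # (sample index, label)
    headpos_pre: np.ndarray                # 3 coils x 3 axes, mm
    headpos_post: np.ndarray
    condition: str
    block_id: int
    array: SensorArray
    head: HeadModel
    truth: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def trial_onsets(self) -> list[int]:
        return [s for s, lab in self.events if lab == "am_onset"]


def _colored_noise(rng: np.random.Generator, shape: tuple[int, ...],
                   fs: float, slope: float = 1.0,
                   knee_hz: float = 5.0) -> np.ndarray:
    """Gaussian noise with amplitude spectrum sqrt(1 + (knee/f)^slope).

    Normalized so the white floor has unit density relative to a unit-SD
    white process.
    """
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1 / fs)
    gain = np.ones_like(freqs)
    nz = freqs > 0
    gain[nz] = np.sqrt(1.0 + (knee_hz / freqs[nz]) ** slope)
    gain[0] = 0.0
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1) * gain
    return np.fft.irfft(spec, n, axis=-1)


def entrained_moment(params: SourceParams, hemisphere: str,
                     stim: StimulusSpec, n_samples: int, onset_sample: int,
                     fs: float = FS_MEG) -> np.ndarray:
    """Deterministic entrained 40-Hz moment course for one stimulus trial.

    The oscillation is phase-locked to each burst onset with the
    participant's phase lag; its amplitude ramps linearly over
    ``buildup_ms`` after the AM onset and after each gap. An optional slow
    damped transient marks the stimulus onset in the quiet condition.
    """
    amp = (params.amplitude_left if hemisphere == "left"
           else params.amplitude_right)
    t = np.arange(n_samples) / fs
    t0 = onset_sample / fs
    lag = params.phase_lag_ms / 1000.0
    out = np.zeros(n_samples)
    period = (stim.burst_ms + stim.gap_ms) / 1000.0
    for k, onset_ms in enumerate(stim.burst_onsets_ms):
        tk = t0 + onset_ms / 1000.0
        seg = (t >= tk) & (t < tk + period)
        tl = t[seg] - tk
        if params.buildup_ms > 0:
            gate = np.clip(tl / (params.buildup_ms / 1000.0), 0.0, 1.0)
        else:
            gate = 1.0
        out[seg] += amp * gate * np.cos(
            2 * np.pi * stim.mod_hz * (tl - lag))
    if params.onset_transient:
        seg = (t >= t0 + 0.03) & (t < t0 + 0.35)
        tl = t[seg] - t0 - 0.03
        out[seg] += 2.0 * amp * np.sin(2 * np.pi * 6.0 * tl) * np.exp(-tl / 0.08)
    return out


def trial_source_waveforms(p: ParticipantSpec, condition: str,
                           stim: StimulusSpec, seed: int,
                           background_rms_nAm: float = 8.0,
                           fs: float = FS_MEG) -> dict[str, np.ndarray]:
    """Left/right moment series for one trial (-500 to +2500 ms).

    Entrained component plus an additive 1/f background; set
    ``background_rms_nAm=0`` for the noiseless response.
    """
    if condition not in p.sources:
        raise KeyError(f"participant has no source parameters for {condition!r}")
    params = p.sources[condition]
    n = int(round((TRIAL_PRE_MS + TRIAL_POST_MS) / 1000.0 * fs))
    onset = int(round(TRIAL_PRE_MS / 1000.0 * fs))
    rng = np.random.default_rng(seed)
    out = {}
    for hemi in ("left", "right"):
        x = entrained_moment(params, hemi, stim, n, onset, fs)
        if background_rms_nAm > 0:
            bg = _colored_noise(rng, (n,), fs, slope=1.0, knee_hz=5.0)
            x = x + background_rms_nAm * bg / np.std(bg)
        out[hemi] = x
    return out


def _blink_artifact(rng: np.random.Generator, n: int, fs: float,
                    array: SensorArray, cfg: ArtifactConfig
                    ) -> tuple[np.ndarray, list[int]]:
    """Frontal slow transients at Poisson times. Returns (channels x n, times)."""
    idx = array.usable_index
    y = array.positions_mm[idx, 1]
    topo = np.exp(-((y.max() - y) ** 2) / (2 * 30.0**2))
    width = int(round(cfg.blink_width_ms / 1000.0 * fs))
    tpl = np.hanning(width) ** 2
    course = np.zeros(n)
    n_blinks = rng.poisson(cfg.blink_rate_hz * n / fs)
    times = sorted(rng.integers(0, max(n - width, 1), size=n_blinks).tolist())
    for s in times:
        course[s : s + width] += tpl[: n - s] * rng.uniform(0.7, 1.3)
    return cfg.blink_amp_fT * 1e-15 * np.outer(topo, course), times


def _cardiac_template(fs: float) -> np.ndarray:
    """Stereotyped multiphasic beat shape, ~120 ms long."""
    t = np.arange(int(0.12 * fs)) / fs - 0.06
    sharp = np.exp(-(t / 0.008) ** 2)
    return (1.2 * sharp - 0.5 * np.roll(sharp, int(0.015 * fs))
            - 0.3 * np.roll(sharp, -int(0.015 * fs))
            + 0.25 * np.exp(-((t - 0.035) / 0.02) ** 2))


def _cardiac_artifact(rng: np.random.Generator, n: int, fs: float,
                      n_chan: int, cfg: ArtifactConfig
                      ) -> tuple[np.ndarray, list[int]]:
    """Quasi-periodic beats with a fixed broad topography."""
    topo = rng.standard_normal(n_chan)
    topo = topo / np.max(np.abs(topo))
    tpl = _cardiac_template(fs)
    course = np.zeros(n)
    mean_ivi = fs / cfg.cardiac_rate_hz
    s = rng.uniform(0, mean_ivi)
    times: list[int] = []
    while s < n - len(tpl):
        si = int(s)
        times.append(si + int(np.argmax(tpl)))
        course[si : si + len(tpl)] += tpl * (
            1.0 + cfg.cardiac_amp_jitter * rng.standard_normal())
        s += mean_ivi * (1.0 + cfg.cardiac_interval_jitter
                         * rng.standard_normal())
    return cfg.cardiac_amp_fT * 1e-15 * np.outer(topo, course), times


def simulate_block(p: ParticipantSpec, condition: str, stim: StimulusSpec,
                   head: HeadModel, array: SensorArray, block_id: int,
                   n_trials: int = 75, seed: int = 0,
                   artifacts: ArtifactConfig | None = None,
                   positions: dict[str, np.ndarray] | None = None,
                   orientations: dict[str, np.ndarray] | None = None
                   ) -> SensorRecording:
    """Simulate one stimulation block (``n_trials`` trials, 4-s spacing)."""
    cfg = artifacts or ArtifactConfig()
    if stim.inter_onset_ms < TRIAL_PRE_MS + TRIAL_POST_MS:
        raise ValueError("inter-onset interval shorter than the trial span")
    fs = FS_MEG
    block_s = n_trials * stim.inter_onset_ms / 1000.0
    n = int(round(block_s * fs))
    rng = np.random.default_rng(seed)
    pos = positions or DEFAULT_POSITIONS_MM
    ori = orientations or DEFAULT_ORIENTATIONS
    params = p.sources[condition]

    onsets = [int(round((TRIAL_PRE_MS + k * stim.inter_onset_ms) / 1000.0 * fs))
              for k in range(n_trials)]
    idx = array.usable_index
    n_chan = len(idx)
    data = np.zeros((n_chan, n))
    moments = {}
    for hemi in ("left", "right"):
        m = np.zeros(n)
        for onset in onsets:
            m += entrained_moment(params, hemi, stim, n, onset, fs)
        if cfg.background_rms_nAm > 0:
            bg = _colored_noise(rng, (n,), fs, slope=1.0, knee_hz=5.0)
            m = m + cfg.background_rms_nAm * bg / np.std(bg)
        pattern = forward_field(pos[hemi], ori[hemi], head, array)
        data += np.outer(pattern, m * 1e0)  # pattern is T per nAm
        moments[hemi] = m

    if cfg.noise_floor_fT_sqrtHz > 0:
        noise = _colored_noise(rng, (n_chan, n), fs, slope=1.0,
                               knee_hz=cfg.pink_knee_hz)
        # scale so the white floor has the requested spectral density
        noise *= cfg.noise_floor_fT_sqrtHz * 1e-15 * np.sqrt(fs / 2)
        data += noise

    blink_times: list[int] = []
    beat_times: list[int] = []
    if cfg.blink_rate_hz > 0:
        art, blink_times = _blink_artifact(rng, n, fs, array, cfg)
        data += art
    if cfg.cardiac_rate_hz > 0:
        art, beat_times = _cardiac_artifact(rng, n, fs, n_chan, cfg)
        data += art

    coils = np.array([[0.0, 100.0, 0.0], [-75.0, 0.0, 0.0], [75.0, 0.0, 0.0]])
    drift = rng.normal(0, cfg.head_drift_mm, size=(3, 3))
    events = [(s, "am_onset") for s in onsets]
    truth = {
        "participant": p.id, "condition": condition,
        "source_params": asdict(params),
        "positions_mm": {k: v.tolist() for k, v in pos.items()},
        "orientations": {k: v.tolist() for k, v in ori.items()},
        "moments_nAm": moments,
        "blink_times": blink_times, "beat_times": beat_times,
        "seed": seed,
    }
    return SensorRecording(
        data=data, fs=fs, events=events, headpos_pre=coils,
        headpos_post=coils + drift, condition=condition, block_id=block_id,
        array=array, head=head, truth=truth)


def simulate_participant(p: ParticipantSpec, stim: StimulusSpec,
                         head: HeadModel, array: SensorArray,
                         blocks_per_condition: int = 4,
                         trials_per_block: int = 75, seed: int = 0,
                         artifacts: ArtifactConfig | None = None
                         ) -> list[SensorRecording]:
    """All blocks for one participant, quiet/noise alternating."""
    pid = int.from_bytes(p.id.encode(), "little") % (2**31)
    ss = np.random.SeedSequence([seed, pid])
    seeds = ss.generate_state(2 * blocks_per_condition)
    out = []
    for b in range(2 * blocks_per_condition):
        condition = "quiet" if b % 2 == 0 else "noise"
        out.append(simulate_block(
            p, condition, stim, head, array, block_id=b,
            n_trials=trials_per_block, seed=int(seeds[b] % (2**31)),
            artifacts=artifacts))
    return out


def simulate_recording(cohort: list[ParticipantSpec], stim: StimulusSpec,
                       head: HeadModel | None = None,
                       array: SensorArray | None = None,
                       blocks_per_condition: int = 4,
                       trials_per_block: int = 75, seed: int = 0,
                       artifacts: ArtifactConfig | None = None):
    """Lazily yield ``(participant, [blocks])`` over a cohort.

    Blocks are generated one participant at a time to bound memory; a full
    8-block participant at 75 trials/block is ~1.8 GB of float64 sensor
    data.
    """
    head = head or HeadModel()
    array = array or SensorArray.ctf_like()
    for p in cohort:
        yield p, simulate_participant(
            p, stim, head, array, blocks_per_condition, trials_per_block,
            seed=seed, artifacts=artifacts)
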