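"""Construction of the 40-Hz amplitude-modulated stimulus and babble masker.

The probe stimulus is a 400-Hz tone, sinusoidally amplitude modulated at
40 Hz between 0 and 100%, presented as five 400-ms bursts separated by
12.5-ms silent gaps (one half modulation period), for a total AM duration of
2050 ms. The masker is multi-talker babble, notch-filtered in the octave
around the carrier (-6 dB at 283/566 Hz, below -60 dB at 400 Hz) so that it
overlaps the probe only informationally, not energetically, and mixed at a
fixed +6 dB signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
from scipy import signal

from .filters import design_notch, apply_zero_phase

__all__ = [
    "StimulusSpec",
    "StimulusTimeline",
    "make_am_stimulus",
    "make_notched_babble",
    "calibrate_and_mix",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of the AM probe and masker.

    Durations in ms, frequencies in Hz. The defaults reproduce the
    five-burst 40-Hz probe: gap_ms must equal half a modulation period so
    that consecutive bursts stay phase-continuous, and each burst must hold
    an integer number of modulation cycles.
    """

    carrier_hz: float = 400.0
    mod_hz: float = 40.0
    mod_depth: float = 1.0
    burst_ms: float = 400.0
    gap_ms: float = 12.5
    n_bursts: int = 5
    inter_onset_ms: float = 4000.0
    noise_lead_ms: float = 500.0
    ramp_ms: float = 200.0
    audio_fs_hz: float = 25_000.0
    snr_db: float = 6.0

    def __post_init__(self) -> None:
        if abs(self.gap_ms - 1000.0 / (2 * self.mod_hz)) > 1e-9:
            raise ValueError("gap_ms must equal half a modulation period")
        cycles = self.burst_ms * self.mod_hz / 1000.0
        if abs(cycles - round(cycles)) > 1e-9:
            raise ValueError("burst_ms must hold an integer number of AM cycles")
        if self.audio_fs_hz <= 2 * (self.carrier_hz + self.mod_hz):
            raise ValueError("audio_fs_hz too low for the carrier + sideband")
        if not 0 < self.mod_depth <= 1:
            raise ValueError("mod_depth must be in (0, 1]")

    @property
    def total_am_ms(self) -> float:
        return self.n_bursts * self.burst_ms + (self.n_bursts - 1) * self.gap_ms

    @property
    def burst_onsets_ms(self) -> list[float]:
        return [k * (self.burst_ms + self.gap_ms) for k in range(self.n_bursts)]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StimulusSpec":
        return cls(**json.loads(text))


@dataclass
class StimulusTimeline:
    """A realized stimulus: waveforms plus labelled event onsets."""

    condition: str  # "quiet" or "noise"
    spec: StimulusSpec
    am_waveform: np.ndarray
    masker_waveform: np.ndarray = field(default_factory=lambda: np.empty(0))
    events: list[tuple[float, str]] = field(default_factory=list)

    @property
    def burst_onsets_ms(self) -> list[float]:
        return self.spec.burst_onsets_ms

    @property
    def total_am_ms(self) -> float:
        return self.spec.total_am_ms

    def mixture(self) -> np.ndarray:
        """AM sound plus masker on a common time axis (masker leads)."""
        if self.masker_waveform.size == 0:
            return self.am_waveform
        fs = self.spec.audio_fs_hz
        lead = int(round(self.spec.noise_lead_ms * fs / 1000.0))
        out = self.masker_waveform.copy()
        out[lead : lead + self.am_waveform.size] += self.am_waveform
        return out

    def events_tsv(self) -> str:
        lines = ["onset_ms\tlabel"]
        lines += [f"{t:g}\t{lab}" for t, lab in self.events]
        return "\n".join(lines) + "\n"


def make_am_stimulus(spec: StimulusSpec) -> StimulusTimeline:
    """Synthesize the five-burst AM probe.

    Within each burst the envelope is the raised cosine
    ``0.5 * (1 - cos(2*pi*f_m*t_local))`` with ``t_local`` measured from the
    burst onset, so modulation starts at zero at every onset and the
    half-period gaps keep bursts mutually phase-continuous.
    """
    fs = spec.audio_fs_hz
    n_total = int(round(spec.total_am_ms * fs / 1000.0))
    t = np.arange(n_total) / fs
    wave = np.zeros(n_total)
    events: list[tuple[float, str]] = []
    for k, onset_ms in enumerate(spec.burst_onsets_ms):
        i0 = int(round(onset_ms * fs / 1000.0))
        n_burst = int(round(spec.burst_ms * fs / 1000.0))
        tl = np.arange(n_burst) / fs
        env = 1.0 - spec.mod_depth * 0.5 * (1.0 + np.cos(2 * np.pi * spec.mod_hz * tl))
        carrier = np.sin(2 * np.pi * spec.carrier_hz * (t[i0 : i0 + n_burst]))
        wave[i0 : i0 + n_burst] = env * carrier
        events.append((onset_ms, f"burst_{k}"))
    return StimulusTimeline("quiet", spec, wave, events=events)


def _speech_shaped_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Noise with a long-term speech-like spectrum: flat to 500 Hz, then
    falling at -9 dB/octave."""
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.ones_like(freqs)
    above = freqs > 500.0
    shape[above] = (freqs[above] / 500.0) ** (-1.5)  # -9 dB/octave in power
    spec = np.fft.rfft(white) * shape
    out = np.fft.irfft(spec, n)
    return out / np.std(out)


def _syllabic_envelope(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Slow (2-8 Hz) positive envelope emulating syllable-rate fluctuation."""
    sos = signal.butter(4, [2.0, 8.0], "bandpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, rng.standard_normal(n))
    env = 1.0 + env / (3 * np.std(env))
    return np.clip(env, 0.05, None)


def make_notched_babble(spec: StimulusSpec, seed: int) -> np.ndarray:
    """Generate the notch-filtered babble surrogate.

    Four independent speech-shaped noise streams, each with its own
    syllabic-rate envelope, are summed and notch-filtered in the octave
    around the AM sound. Cosine on/off ramps of ``ramp_ms`` shape the burst.
    Only the spectral (notch) and level (SNR) contracts are guaranteed; this
    is a statistical surrogate, not recorded speech.
    """
    fs = spec.audio_fs_hz
    dur_ms = spec.total_am_ms + 2 * spec.noise_lead_ms
    n = int(round(dur_ms * fs / 1000.0))
    rng = np.random.default_rng(seed)
    babble = np.zeros(n)
    for _ in range(4):
        babble += _speech_shaped_noise(n, fs, rng) * _syllabic_envelope(n, fs, rng)
    taps = design_notch(fs)
    babble = apply_zero_phase(babble, taps)
    n_ramp = int(round(spec.ramp_ms * fs / 1000.0))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    babble[:n_ramp] *= ramp
    babble[-n_ramp:] *= ramp[::-1]
    return babble


def calibrate_and_mix(
    am: np.ndarray, masker: np.ndarray, snr_db: float, spec: StimulusSpec
) -> StimulusTimeline:
    """Rescale the masker for the requested SNR and assemble the noise trial.

    SNR is defined as ``10*log10(P_am / P_masker)`` with both powers taken
    over the interval during which the AM sound plays. The AM waveform is
    never rescaled.
    """
    fs = spec.audio_fs_hz
    lead = int(round(spec.noise_lead_ms * fs / 1000.0))
    seg = masker[lead : lead + am.size]
    p_masker = float(np.mean(seg**2))
    if p_masker <= 0:
        raise ValueError("masker has zero power over the AM interval")
    p_am = float(np.mean(am**2))
    scale = np.sqrt(p_am / p_masker / 10 ** (snr_db / 10.0))
    timeline = make_am_stimulus(spec)
    out = StimulusTimeline(
        "noise", spec, am.copy(), masker_waveform=masker * scale,
        events=list(timeline.events),
    )
    out.events.insert(0, (-spec.noise_lead_ms, "masker_on"))
    return out


def realized_snr_db(timeline: StimulusTimeline) -> float:
    """Measure the AM-interval SNR of a noise-condition timeline in dB."""
    spec = timeline.spec
    fs = spec.audio_fs_hz
    lead = int(round(spec.noise_lead_ms * fs / 1000.0))
    seg = timeline.masker_waveform[lead : lead + timeline.am_waveform.size]
    return float(
        10 * np.log10(np.mean(timeline.am_waveform**2) / np.mean(seg**2))
    )
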