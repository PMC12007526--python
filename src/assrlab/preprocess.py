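"""Artifact screening and removal.

Three steps, applied without rejecting any trials:

1. motion screen — a block is discarded if any head-coil coordinate moved
   by more than 4 mm between the pre- and post-block position measurements;
2. ocular cleanup — ICA on the 20 most frontal channels, selection of the
   two components with blink/eye-movement character, 6-Hz low-pass of their
   waveforms, and regression of those slow waveforms out of every channel
   (the low-pass protects the 40-Hz band from any broadband leakage);
3. cardiac cleanup — ICA on all channels, selection of the component with
   the strongest periodicity in the 0.6-1.6 s quefrency range of its real
   cepstrum, beat detection on that component, and subtraction of a
   beat-locked artifact template at every detected beat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA

from .simulate import SensorRecording

__all__ = ["MotionReport", "ArtifactModel", "screen_head_motion",
           "remove_ocular", "remove_cardiac"]

MOTION_LIMIT_MM = 4.0


@dataclass
class MotionReport:
    displacement_mm: np.ndarray  # coils x axes, absolute pre/post difference
    keep: bool

    @property
    def max_displacement_mm(self) -> float:
        return float(np.max(self.displacement_mm))

    def to_tsv(self) -> str:
        lines = ["coil\tdx_mm\tdy_mm\tdz_mm"]
        for i, row in enumerate(self.displacement_mm):
            lines.append(f"{i}\t" + "\t".join(f"{v:.3f}" for v in row))
        lines.append(f"decision\t{'keep' if self.keep else 'reject'}")
        return "\n".join(lines) + "\n"


@dataclass
class ArtifactModel:
    kind: str                                  # "ocular" | "cardiac"
    component_waveforms: np.ndarray            # components x samples
    regressors: np.ndarray                     # filtered waveforms used
    coefficients: np.ndarray                   # channels x components
    beat_times: list[int] = field(default_factory=list)


def screen_head_motion(recording: SensorRecording) -> MotionReport:
    """Reject a block whose head position drifted > 4 mm on any coil axis.

    The comparison is strict ("larger than"): a displacement of exactly
    4.0 mm is kept.
    """
    if recording.headpos_pre is None or recording.headpos_post is None:
        raise ValueError("both pre- and post-block head positions are required")
    disp = np.abs(np.asarray(recording.headpos_post, float)
                  - np.asarray(recording.headpos_pre, float))
    return MotionReport(displacement_mm=disp,
                        keep=bool(np.max(disp) <= MOTION_LIMIT_MM))


def _frontal_channels(recording: SensorRecording, n: int = 20) -> np.ndarray:
    """Indices (into the usable-channel rows) of the n most anterior sensors."""
    idx = recording.array.usable_index
    y = recording.array.positions_mm[idx, 1]
    return np.argsort(y)[::-1][:n]


def _regress_out(data: np.ndarray, regressors: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """OLS-remove ``regressors`` (k x n) from every channel of ``data``."""
    R = np.atleast_2d(regressors)
    beta, *_ = np.linalg.lstsq(R.T, data.T, rcond=None)
    return data - beta.T @ R, beta.T


def remove_ocular(recording: SensorRecording, n_frontal: int = 20,
                  n_select: int = 2, seed: int = 0
                  ) -> tuple[SensorRecording, ArtifactModel]:
    """Remove blink/eye-movement activity by frontal ICA regression.

    Components are ranked by the product of waveform kurtosis (blinks are
    sparse, high-kurtosis events) and the fraction of their power below
    6 Hz; the top ``n_select`` are kept, low-pass filtered at 6 Hz, and
    regressed out of all channels.
    """
    front = _frontal_channels(recording, n_frontal)
    if len(front) < n_frontal:
        raise ValueError("not enough frontal channels")
    X = recording.data[front]
    X = X - X.mean(axis=1, keepdims=True)
    n_comp = min(n_frontal, 12)
    try:
        S = _decimated_ica(X, n_components=n_comp, seed=seed)
    except Exception as exc:  # pragma: no cover - decomposition failure
        raise RuntimeError("frontal ICA decomposition failed") from exc

    fs = recording.fs
    freqs = np.fft.rfftfreq(S.shape[1], 1 / fs)
    psd = np.abs(np.fft.rfft(S, axis=1)) ** 2
    low = psd[:, freqs <= 6.0].sum(axis=1) / psd.sum(axis=1)
    centered = S - S.mean(axis=1, keepdims=True)
    kurt = (centered**4).mean(axis=1) / (centered**2).mean(axis=1) ** 2 - 3.0
    score = np.clip(kurt, 0, None) * low
    order = np.argsort(score)[::-1]
    plausible = [i for i in order[:n_select] if score[i] > 0.1]
    if len(plausible) < n_select:
        warnings.warn("fewer than 2 plausible ocular components found; "
                      "regressing what was found", stacklevel=2)
    if not plausible:
        model = ArtifactModel("ocular", np.empty((0, S.shape[1])),
                              np.empty((0, S.shape[1])),
                              np.zeros((recording.data.shape[0], 0)))
        return recording, model

    sos = signal.butter(4, 6.0, "lowpass", fs=fs, output="sos")
    regressors = signal.sosfiltfilt(sos, S[plausible], axis=1)
    cleaned, beta = _regress_out(recording.data, regressors)
    out = SensorRecording(
        data=cleaned, fs=recording.fs, events=recording.events,
        headpos_pre=recording.headpos_pre, headpos_post=recording.headpos_post,
        condition=recording.condition, block_id=recording.block_id,
        array=recording.array, head=recording.head, truth=recording.truth)
    model = ArtifactModel("ocular", S[plausible], regressors, beta)
    return out, model


def _stimulus_locked_model(recording: SensorRecording) -> np.ndarray:
    """Trial-onset-locked average placed back at every trial onset."""
    onsets = recording.trial_onsets
    if len(onsets) < 2:
        return np.zeros_like(recording.data)
    span = min(int(np.min(np.diff(onsets))),
               recording.n_samples - max(onsets))
    segs = np.stack([recording.data[:, s : s + span] for s in onsets
                     if s + span <= recording.n_samples])
    evoked = segs.mean(axis=0)
    evoked = evoked - evoked.mean(axis=1, keepdims=True)
    model = np.zeros_like(recording.data)
    for s in onsets:
        model[:, s : s + span] += evoked[:, : recording.n_samples - s]
    return model


def _decimated_ica(X: np.ndarray, n_components: int, seed: int,
                   factor: int = 5) -> np.ndarray:
    """FastICA with the unmixing matrix estimated on decimated data.

    The mixing is instantaneous, so unmixing weights estimated at a reduced
    rate apply unchanged at the full rate; this cuts the decomposition cost
    by the decimation factor. Returns component waveforms at the full rate.
    """
    Xd = signal.decimate(X, factor, axis=1, zero_phase=True)
    ica = FastICA(n_components=n_components, random_state=seed,
                  max_iter=1000, whiten="unit-variance", tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ica.fit(Xd.T)
    return ica.components_ @ X


def _cepstral_peak(x: np.ndarray, fs: float, q_lo: float = 0.6,
                   q_hi: float = 1.6, smooth: int = 41
                   ) -> tuple[float, float]:
    """(robust peak score, quefrency s) of periodicity in [q_lo, q_hi].

    Real cepstrum of the Welch-averaged log spectrum of the waveform's
    energy envelope. The envelope is used because beat-interval jitter
    scrambles the phase of the high harmonics that carry the multiphasic
    beat waveform, while the beat-rate fundamental of the energy envelope
    survives. The cepstrum is smoothed to match the jitter-broadened peak,
    and the score is the peak height over the surrounding quefrency
    background in robust (MAD) standard deviations.
    """
    env = np.abs(signal.hilbert(x))
    env = env - env.mean()
    nperseg = min(2**15, len(env))
    _, pxx = signal.welch(env, fs=fs, nperseg=nperseg)
    logp = np.log(np.maximum(pxx, 1e-300))
    ceps = np.fft.irfft(logp - logp.mean())
    ceps = np.convolve(ceps, np.ones(smooth) / smooth, mode="same")
    q = np.arange(len(ceps)) / fs
    band = (q >= q_lo) & (q <= q_hi)
    seg = ceps[band]
    i = int(np.argmax(seg))
    bg = seg[np.abs(np.arange(len(seg)) - i) > 2 * smooth]
    mad = 1.4826 * np.median(np.abs(bg - np.median(bg)))
    if mad == 0:
        return 0.0, 0.0
    return float((seg[i] - np.median(bg)) / mad), float(q[band][i])


def remove_cardiac(recording: SensorRecording, n_components: int = 30,
                   z_threshold: float = 8.0, seed: int = 0
                   ) -> tuple[SensorRecording, ArtifactModel]:
    """Remove the heartbeat artifact by cepstrum-guided template regression.

    ICA over all channels; the component whose cepstrum has the strongest
    peak at heartbeat quefrencies (0.6-1.6 s) marks the beats. The
    beat-locked sensor average forms a template which is subtracted, per
    channel and least-squares scaled, at every beat. If no component passes
    the ``z_threshold``, the recording is returned unchanged with a
    warning. The threshold sits well above the maximum score that pure
    noise components reach and well below that of genuine beat trains.
    """
    if recording.n_samples < 60 * recording.fs:
        raise ValueError("need at least 60 s for a stable periodicity estimate")
    X = recording.data - recording.data.mean(axis=1, keepdims=True)
    n_comp = min(n_components, recording.data.shape[0])
    S = _decimated_ica(X, n_components=n_comp, seed=seed)

    scores = [_cepstral_peak(s, recording.fs) for s in S]
    z = np.array([s[0] for s in scores])
    best = int(np.argmax(z))
    if z[best] < z_threshold:
        warnings.warn("no component with heartbeat periodicity above "
                      "threshold; cardiac removal skipped", stacklevel=2)
        model = ArtifactModel("cardiac", np.empty((0, S.shape[1])),
                              np.empty((0, S.shape[1])),
                              np.zeros((recording.data.shape[0], 0)))
        return recording, model

    quefrency = scores[best][1]
    comp = S[best] * np.sign(np.mean(S[best] ** 3))  # orient sharp peaks up
    min_dist = int(0.6 * quefrency * recording.fs)
    peaks, _ = signal.find_peaks(comp, distance=min_dist,
                                 height=3.0 * np.std(comp))
    if len(peaks) < 5:
        peaks, _ = signal.find_peaks(-comp, distance=min_dist,
                                     height=3.0 * np.std(comp))
    half = int(0.1 * recording.fs)
    good = peaks[(peaks > half) & (peaks < recording.n_samples - half)]

    # the beat-locked average must not absorb the stimulus-locked evoked
    # response, so the template is estimated on the trial-evoked residual
    residual = recording.data - _stimulus_locked_model(recording)
    segs = np.stack([residual[:, p - half : p + half] for p in good])
    template = segs.mean(axis=0)
    template -= template.mean(axis=1, keepdims=True)

    # build the artifact time course and scale per channel
    artifact = np.zeros_like(recording.data)
    for p in good:
        artifact[:, p - half : p + half] += template
    num = np.einsum("ij,ij->i", residual, artifact)
    den = np.einsum("ij,ij->i", artifact, artifact)
    scale = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    cleaned = recording.data - scale[:, None] * artifact

    out = SensorRecording(
        data=cleaned, fs=recording.fs, events=recording.events,
        headpos_pre=recording.headpos_pre, headpos_post=recording.headpos_post,
        condition=recording.condition, block_id=recording.block_id,
        array=recording.array, head=recording.head, truth=recording.truth)
    model = ArtifactModel("cardiac", S[best : best + 1],
                          comp[None, :], scale[:, None],
                          beat_times=good.tolist())
    return out, model
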