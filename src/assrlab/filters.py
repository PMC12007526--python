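"""FIR filter design and zero-phase application helpers.

Two filters matter for the 40-Hz steady-state pipeline: the octave-wide
band-pass (28-56 Hz) applied to source waveforms before the Hilbert
transform, and the deep notch that removes the 283-566 Hz octave from the
babble masker so that it cannot energetically mask the AM tone.

All filters here are applied with exactly zero phase: the signal spectrum is
multiplied by the magnitude response of the designed FIR. For a linear-phase
FIR this equals applying the filter and removing its (possibly fractional)
group delay, and it keeps response-latency estimates free of filter delay.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = [
    "design_bandpass",
    "design_notch",
    "apply_zero_phase",
    "measure_gain_db",
    "measure_edge_hz",
]


def apply_zero_phase(x: np.ndarray, taps: np.ndarray, axis: int = -1) -> np.ndarray:
    """Filter ``x`` with the magnitude response of ``taps`` at zero phase.

    Implemented in the frequency domain: Y(f) = X(f) * |H(f)|. The input
    length is preserved and no group delay is introduced.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    nfft = int(2 ** np.ceil(np.log2(max(2 * n, 2 * len(taps)))))
    h = np.abs(np.fft.rfft(taps, nfft))
    X = np.fft.rfft(x, nfft, axis=axis)
    shape = [1] * x.ndim
    shape[axis] = len(h)
    y = np.fft.irfft(X * h.reshape(shape), nfft, axis=axis)
    return np.take(y, np.arange(n), axis=axis)


def measure_gain_db(taps: np.ndarray, freq_hz: float, fs: float) -> float:
    """Magnitude response of the FIR at a single frequency, in dB."""
    _, h = signal.freqz(taps, worN=[freq_hz], fs=fs)
    return float(20 * np.log10(np.abs(h[0])))


def measure_edge_hz(
    taps: np.ndarray, fs: float, target_db: float, lo: float, hi: float
) -> float:
    """Locate the frequency in [lo, hi] where the gain crosses ``target_db``.

    Assumes the response is monotonic across the bracket (a filter edge).
    """
    f = np.linspace(lo, hi, 4001)
    _, h = signal.freqz(taps, worN=f, fs=fs)
    g = 20 * np.log10(np.maximum(np.abs(h), 1e-300))
    idx = np.argmin(np.abs(g - target_db))
    return float(f[idx])


def _tune_cutoff(
    fs: float, numtaps: int, edge: float, band: tuple[float, float], side: str
) -> float:
    """Find the firwin cutoff putting the -3 dB point of a band edge at ``edge``.

    firwin places -6 dB at its cutoff; the -3 dB point sits slightly inside
    the passband. A short bisection on the cutoff fixes the offset.
    """
    lo_c, hi_c = band

    def edge_at(cut: float) -> float:
        cuts = [cut, hi_c] if side == "lo" else [lo_c, cut]
        taps = signal.firwin(numtaps, cuts, pass_zero=False, fs=fs)
        bracket = (cut * 0.7, cut * 1.3)
        return measure_edge_hz(taps, fs, -3.0, *bracket)

    # the measured -3 dB edge rises monotonically with the cutoff on
    # either side of the passband
    a, b = edge * 0.8, edge * 1.2
    for _ in range(40):
        m = 0.5 * (a + b)
        if edge_at(m) < edge:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def design_bandpass(
    fs: float, f_lo: float = 28.0, f_hi: float = 56.0, numtaps: int = 512
) -> np.ndarray:
    """One-octave band-pass FIR with -3 dB edges at ``f_lo`` and ``f_hi``.

    The default 512-tap length at 1250 Hz gives a narrow transition so the
    -3 dB points can be placed to better than 0.5 Hz.
    """
    c_lo = _tune_cutoff(fs, numtaps, f_lo, (f_lo, f_hi), "lo")
    c_hi = _tune_cutoff(fs, numtaps, f_hi, (f_lo, f_hi), "hi")
    return signal.firwin(numtaps, [c_lo, c_hi], pass_zero=False, fs=fs)


def design_notch(
    fs: float,
    f_lo: float = 283.0,
    f_hi: float = 566.0,
    center_hz: float = 400.0,
    min_center_atten_db: float = 60.0,
    numtaps: int = 3001,
) -> np.ndarray:
    """Band-stop FIR: -6 dB at the octave edges, deep rejection at the center.

    Raises ``ValueError`` if the realized response misses the template
    (center attenuation or edge placement), rather than degrading silently.
    """
    taps = signal.firwin(
        numtaps, [f_lo, f_hi], pass_zero=True, window=("kaiser", 9.0), fs=fs
    )
    center_db = measure_gain_db(taps, center_hz, fs)
    if center_db > -min_center_atten_db:
        raise ValueError(
            f"notch attenuation at {center_hz} Hz is {center_db:.1f} dB, "
            f"needs <= -{min_center_atten_db} dB; increase numtaps"
        )
    for edge in (f_lo, f_hi):
        realized = measure_edge_hz(taps, fs, -6.0, edge * 0.85, edge * 1.15)
        if abs(realized - edge) > 0.02 * edge:
            raise ValueError(
                f"notch -6 dB edge at {realized:.1f} Hz, expected {edge} Hz"
            )
    return taps
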