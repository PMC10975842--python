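"""Signal-fidelity metrics: RMSE, PRD, normalized PSD error, STFT grid.

RMSE is the plain root-mean-square sample error between a transformed and
an original signal.  PRD normalizes it by the RMS of the original and is
the standard figure of merit for ECG reconstruction fidelity:

    PRD = RMSE(transformed, original) / RMS(original) * 100 %

The normalized PSD error compares Welch spectra bin-by-bin on a 0.2 Hz
grid over 0-100 Hz, normalized by the single largest PSD value found in
either spectrum so that records of different amplitude compare fairly:

    err(f) = |PSD_x(f) - PSD_y(f)| / max(PSD_x, PSD_y) * 100 %
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .records import AudioStream


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square error between two equal-length signals.

    Symmetric in its arguments; the result carries the input units.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def prd(transformed: np.ndarray, original: np.ndarray) -> float:
    """Percentage root-mean-square difference of a reconstruction (%)."""
    original = np.asarray(original, dtype=float)
    rms_ref = np.sqrt(np.mean(original ** 2))
    if rms_ref == 0:
        raise ValueError("PRD undefined for an all-zero original signal")
    return rmse(transformed, original) / rms_ref * 100.0


@dataclass
class PSDError:
    """Per-bin normalized PSD error on a 0-100 Hz, 0.2 Hz grid."""

    freqs_hz: np.ndarray
    error_pct: np.ndarray
    psd_x: np.ndarray
    psd_y: np.ndarray

    def median(self) -> float:
        return float(np.median(self.error_pct))

    def peak(self) -> float:
        return float(np.max(self.error_pct))


def normalized_psd_error(x: np.ndarray, y: np.ndarray, fs: float,
                         f_max: float = 100.0,
                         bin_hz: float = 0.2) -> PSDError:
    """Welch-PSD comparison of two signals on a fixed frequency grid.

    Welch segments of ``1/bin_hz`` seconds (Hann window, 50 % overlap)
    realize ``bin_hz``-wide bins; the error is normalized by the global
    maximum over both PSDs, so it lies in [0, 100] by construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if fs < 2 * f_max:
        raise ValueError(f"fs = {fs} Hz too low for the 0-{f_max} Hz range")
    nperseg = int(round(fs / bin_hz))
    if x.size < nperseg:
        raise ValueError(
            f"record too short for one Welch segment ({nperseg} samples)")
    f, pxx = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2)
    _, pyy = sps.welch(y, fs=fs, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2)
    keep = f <= f_max
    f, pxx, pyy = f[keep], pxx[keep], pyy[keep]
    norm = max(float(np.max(pxx)), float(np.max(pyy)))
    if norm == 0:
        err = np.zeros_like(pxx)
    else:
        err = np.abs(pxx - pyy) / norm * 100.0
    return PSDError(f, err, pxx, pyy)


def spectrogram(audio: AudioStream, window_s: float = 1.0,
                overlap_frac: float = 0.5):
    """STFT magnitude grid of the audio stream.

    Default framing is a 1 s window advanced by half a window, so a 10 s
    stream yields 19 frames.  Returns ``(freqs_hz, times_s, magnitude)``
    with magnitude shaped (n_freqs, n_frames).
    """
    nperseg = int(round(window_s * audio.fs))
    if audio.n_samples < nperseg:
        raise ValueError(
            f"audio shorter than one window ({nperseg} samples)")
    noverlap = int(round(overlap_frac * nperseg))
    f, t, mag = sps.spectrogram(audio.samples, fs=audio.fs, window="hann",
                                nperseg=nperseg, noverlap=noverlap,
                                mode="magnitude")
    return f, t, mag


def carrier_peaks(audio: AudioStream, n_peaks: int = 8,
                  min_separation_hz: float = 100.0) -> np.ndarray:
    """Frequencies of the strongest spectral peaks of a stream, ascending.

    Used to verify the carrier layout of a sonified stream: a zero-input
    sonification must show exactly the eight carrier tones.
    """
    spec = np.abs(np.fft.rfft(audio.samples))
    freqs = np.fft.rfftfreq(audio.n_samples, d=1.0 / audio.fs)
    min_sep = int(round(min_separation_hz / (freqs[1] - freqs[0])))
    idx, _ = sps.find_peaks(spec, distance=max(min_sep, 1))
    if idx.size < n_peaks:
        raise ValueError(f"found only {idx.size} spectral peaks")
    top = idx[np.argsort(spec[idx])[-n_peaks:]]
    return np.sort(freqs[top])
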